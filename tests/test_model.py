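import numpy as np
import pytest

import retropbtk as rk
from retropbtk.model import (I_E_GUT, I_E_LIV, N_STATE, _Compiled,
                             extended_liver_clearance, retrorsine_rhs)


class TestExtendedClearance:
    def test_reported_liver_clearance(self, sub, phys):
        assert extended_liver_clearance(sub, phys) == pytest.approx(9.08, rel=0.02)

    def test_no_uptake_no_clearance(self, sub, phys):
        assert extended_liver_clearance(sub.with_overrides(cl_act_in=0.0), phys) == 0.0

    def test_flow_limited_asymptote(self, sub, phys):
        """Unbounded uptake makes the liver flow-limited: CL -> Q_liv / BW."""
        fast = sub.with_overrides(cl_act_in=sub.cl_act_in * 1e6)
        q_ml_min_kg = phys.liver_blood_flow * 1000 / 60 / phys.body_weight
        assert extended_liver_clearance(fast, phys) == pytest.approx(
            q_ml_min_kg, rel=1e-3)


class TestUnitConversions:
    def test_whole_organ_rates(self, sub, phys):
        c = _Compiled(sub, phys, None)
        # renal: 0.9 mL/min/kg * 73 kg -> L/h
        assert c.cl_renal == pytest.approx(0.9 * 73 * 60 / 1000)
        # hepatic intrinsic metabolic clearance: (26.2/25.5) mL/min/g * 1800 g
        assert c.vmax_liv / c.km_liv == pytest.approx(26.2 / 25.5 * 1800 * 60 / 1000,
                                                      rel=1e-12)
        # gut metabolic clearance honors the reported 1.35 mL/min/kg
        assert c.vmax_gut / c.km_gut / phys.body_weight * 1000 / 60 == \
            pytest.approx(1.35, rel=0.005)


class TestRhs:
    def test_zero_state_zero_derivatives(self, sub, phys):
        dy = retrorsine_rhs(0.0, np.zeros(14), sub, phys)
        assert np.all(dy == 0.0)

    def test_invalid_states_rejected(self, sub, phys):
        bad = np.zeros(N_STATE)
        bad[2] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            retrorsine_rhs(0.0, bad, sub, phys)
        neg = np.zeros(N_STATE)
        neg[2] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            retrorsine_rhs(0.0, neg, sub, phys)


class TestSimulation:
    def test_mass_balance(self, single_dose_sim):
        """Dose = body burden + all cumulative eliminations at every time."""
        resid = 100.0 - single_dose_sim.body_amount() - single_dose_sim.eliminated()
        assert np.abs(resid).max() < 1e-6 * 100.0

    def test_trajectories_nonnegative_and_cums_monotone(self, single_dose_sim):
        for traj in single_dose_sim.amounts.values():
            assert traj.min() > -1e-9
        for cum in single_dose_sim.cumulative.values():
            assert np.all(np.diff(cum) > -1e-9)

    def test_no_doses_identically_zero(self, sub, phys):
        out = rk.simulate([], sub, phys, t_end=10.0)
        assert np.all(out.body_amount() == 0.0)
        assert np.all(out.eliminated() == 0.0)
        assert np.all(out.states[I_E_LIV] == 1.0)
        assert np.all(out.states[I_E_GUT] == 1.0)

    def test_dose_proportionality_in_linear_range(self, sub, phys, single_dose_sim):
        half = rk.simulate([rk.DoseRegimen("retrorsine", 50.0, (0.0,), "oral")],
                           sub, phys, t_end=48.0)
        for matrix in ("plasma", "liver", "gut"):
            auc_full = np.trapezoid(single_dose_sim.concentration(matrix),
                                    single_dose_sim.time)
            auc_half = np.trapezoid(half.concentration(matrix), half.time)
            assert auc_full == pytest.approx(2 * auc_half, rel=1e-3)
            assert single_dose_sim.concentration(matrix).max() == pytest.approx(
                2 * half.concentration(matrix).max(), rel=1e-3)

    def test_closed_form_clearance_matches_iv_simulation(self, sub, phys):
        """Eq-style hepatic clearance vs clearance inferred from an IV dose.

        Gut metabolism is switched off in the oracle run so the portal
        inflow is undepleted and the liver is the only metabolic organ.
        """
        sub_h = sub.with_overrides(vmax_gut=0.0)
        iv = rk.simulate([rk.DoseRegimen("retrorsine", 100.0, (0.0,), "iv")],
                         sub_h, phys, t_end=96.0)
        auc = iv.cumulative["cum_renal"][-1] / (sub.cl_renal * 73 * 60 / 1000)
        liv_met = (iv.cumulative["cum_met_cyp3a4_liv"][-1]
                   + iv.cumulative["cum_met_other_liv"][-1])
        cl_sim = liv_met / auc  # L/h referenced to venous plasma
        cl_closed = extended_liver_clearance(sub, phys) * 73 * 60 / 1000
        assert cl_sim == pytest.approx(cl_closed, rel=0.02)

    def test_t_end_before_last_dose_rejected(self, sub, phys):
        with pytest.raises(ValueError, match="t_end"):
            rk.simulate([rk.DoseRegimen("retrorsine", 1.0, (0.0, 48.0), "oral")],
                        sub, phys, t_end=24.0)


class TestBioavailability:
    def test_decomposition_product_identity(self, bioavailability):
        f, fa, fg, fh = bioavailability
        assert f == pytest.approx(fa * fg * fh, rel=1e-9)

    def test_fraction_absorbed_is_substance_parameter(self, bioavailability, sub):
        assert bioavailability[1] == sub.f_a


class TestBiodistribution:
    def test_route_shares_sum_to_one(self, single_dose_sim):
        rep = rk.biodistribution_report(single_dose_sim, 100.0)
        assert sum(rep["route_shares"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_peak_fractions_are_fractions(self, single_dose_sim):
        rep = rk.biodistribution_report(single_dose_sim, 100.0)
        for name, frac in rep["tissue_peak_fraction"].items():
            # the lumen holds exactly the full dose at t = 0
            assert 0.0 <= frac <= 1.0, name


class TestDoseRegimen:
    def test_validation(self):
        with pytest.raises(ValueError):
            rk.DoseRegimen("retrorsine", -1.0, (0.0,))
        with pytest.raises(ValueError):
            rk.DoseRegimen("retrorsine", 1.0, (24.0, 0.0))
        with pytest.raises(ValueError):
            rk.DoseRegimen("caffeine", 1.0, (0.0,))
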