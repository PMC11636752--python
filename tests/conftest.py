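"""Shared fixtures: reference parameter sets and the expensive scenario runs."""

import pytest

import retropbtk as rk
from retropbtk import scenarios as sc


@pytest.fixture(scope="session")
def phys():
    return rk.build_reference_human()


@pytest.fixture(scope="session")
def sub():
    return rk.retrorsine_reference()


@pytest.fixture(scope="session")
def single_dose_sim(sub, phys):
    """Single 100 nmol oral dose followed for 48 h."""
    reg = rk.DoseRegimen("retrorsine", 100.0, (0.0,), "oral")
    return rk.simulate([reg], sub, phys, t_end=48.0)


@pytest.fixture(scope="session")
def tea_sim(sub, phys):
    """Five weeks of daily herbal-tea dosing, no perpetrator."""
    return sc.run_scenario(rk.ScenarioSpec("herbal_tea"), sub, phys)


@pytest.fixture(scope="session")
def rif_sim(sub, phys):
    """Herbal tea plus the two-week rifampicin course (600 mg/day, day 4)."""
    return sc.run_scenario(rk.ScenarioSpec("herbal_tea_plus_rifampicin"), sub, phys)


@pytest.fixture(scope="session")
def bioavailability(sub, phys):
    return rk.bioavailability_decomposition(sub, phys)


@pytest.fixture(scope="session")
def tea_sensitivity(sub, phys):
    """Tea-only sensitivity run: f_m acts multiplicatively, K_i is inactive."""
    return sc.sensitivity_coefficients(
        rk.ScenarioSpec("herbal_tea"), sub, phys, params=("fm_cyp3a4", "ki"))
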