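"""Exposure scenarios, 24-h window metrics, interaction ratios and sensitivity.

The two study scenarios are five weeks of daily herbal-tea consumption
(retrorsine 0.019 µg/kg/day) alone, and the same tea intake combined with a
two-week therapeutic course of rifampicin (600 mg/day starting on day 4).
Exposure is summarized per 24-h window as AUC24 and Cmax in plasma, liver
cellular space and gut tissue, plus daily and cumulative pathway-resolved
metabolite formation; the interaction is quantified as percent-of-reference
ratios against the rifampicin-free scenario. A local sensitivity analysis
perturbs the four interaction parameters by ±10% and reports normalized
sensitivity coefficients on the cumulative CYP3A4 metabolite amounts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ddi
from .model import DoseRegimen, SimOutput, simulate
from .physiology import PhysiologyParams
from .substance import SubstanceParams

__all__ = [
    "ScenarioSpec",
    "make_scenario",
    "run_scenario",
    "day_windows",
    "auc_cmax_by_day",
    "metabolite_formation_report",
    "interaction_ratio_table",
    "sensitivity_coefficients",
]

MATRICES = ("plasma", "liver", "gut")


@dataclass(frozen=True)
class ScenarioSpec:
    """Dosing layout of one exposure scenario.

    ``rif_start_day`` is 1-based: day 4 means the rifampicin course starts
    72 h after the first tea dose.
    """

    name: str = "herbal_tea"
    tea_dose_ug_per_kg: float = 0.019
    tea_days: int = 35
    rif_dose_mg: float = 600.0
    rif_start_day: int = 4
    rif_days: int = 14

    def __post_init__(self) -> None:
        if self.name not in ("herbal_tea", "herbal_tea_plus_rifampicin"):
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.with_rifampicin:
            if self.rif_start_day < 1 or (
                    self.rif_start_day - 1 + self.rif_days > self.tea_days):
                raise ValueError("rifampicin window must lie within the tea window")

    @property
    def with_rifampicin(self) -> bool:
        return self.name == "herbal_tea_plus_rifampicin"

    @property
    def rif_first_dose_h(self) -> float:
        return (self.rif_start_day - 1) * 24.0

    @property
    def rif_last_dose_h(self) -> float:
        return self.rif_first_dose_h + (self.rif_days - 1) * 24.0


def make_scenario(spec: ScenarioSpec, sub: SubstanceParams,
                  phys: PhysiologyParams) -> list[DoseRegimen]:
    """Dose regimens of a scenario; tea dose converted µg/kg/day → nmol/day."""
    dose_nmol = (spec.tea_dose_ug_per_kg * phys.body_weight
                 / sub.mol_weight * 1000.0)
    tea_times = tuple(24.0 * d for d in range(spec.tea_days))
    regimens = [DoseRegimen("retrorsine", dose_nmol, tea_times, "oral")]
    if spec.with_rifampicin:
        rif_times = tuple(spec.rif_first_dose_h + 24.0 * d
                          for d in range(spec.rif_days))
        regimens.append(DoseRegimen("rifampicin", spec.rif_dose_mg, rif_times, "oral"))
    return regimens


def run_scenario(spec: ScenarioSpec, sub: SubstanceParams, phys: PhysiologyParams,
                 rifp: ddi.Rif2CompParams | None = None,
                 ip: ddi.InductionParams | None = None,
                 t_end: float | None = None, **solver_options) -> SimOutput:
    """Simulate a scenario; the rifampicin layer is attached only when dosed."""
    regimens = make_scenario(spec, sub, phys)
    t_end = t_end if t_end is not None else spec.tea_days * 24.0
    if spec.with_rifampicin:
        tea, rif = regimens
        return ddi.coupled_simulate(tea, rif, sub, phys, rifp=rifp, ip=ip,
                                    t_end=t_end, **solver_options)
    return simulate(regimens, sub, phys, t_end=t_end, **solver_options)


def day_windows(spec: ScenarioSpec) -> dict[str, tuple[float, float]]:
    """Named 24-h windows: day k after the first / last rifampicin dose.

    "Day k after the first (last) dose" is the window starting at the first
    (last) rifampicin dose time plus (k−1)·24 h, so day 1 after the last
    dose covers the 24 h right after that dose — consistent with the
    maximal enzyme induction falling on "day 1 after the last dose". The
    tea-only reference day is day 3 of dosing (kinetics equilibrate within
    hours given the sub-day washout).
    """
    windows = {"reference": (48.0, 72.0)}
    if spec.with_rifampicin:
        t0, tl = spec.rif_first_dose_h, spec.rif_last_dose_h
        for k in (1, 3, 14):
            windows[f"day_{k}_after_first_dose"] = (t0 + (k - 1) * 24.0, t0 + k * 24.0)
        for k in (2, 6, 14):
            windows[f"day_{k}_after_last_dose"] = (tl + (k - 1) * 24.0, tl + k * 24.0)
    return windows


def _window_slice(simout: SimOutput, lo: float, hi: float) -> np.ndarray:
    mask = (simout.time >= lo - 1e-9) & (simout.time <= hi + 1e-9)
    if simout.time[mask].size < 3 or hi > simout.time[-1] + 1e-9:
        raise ValueError(f"window [{lo}, {hi}] h not densely covered by the simulation")
    return mask


def auc_cmax_by_day(simout: SimOutput, windows: dict[str, tuple[float, float]],
                    matrices=MATRICES) -> pd.DataFrame:
    """Trapezoidal AUC24 (nmol/L·h) and Cmax (nmol/L) per window and matrix."""
    rows = []
    for label, (lo, hi) in windows.items():
        mask = _window_slice(simout, lo, hi)
        t = simout.time[mask]
        for matrix in matrices:
            conc = simout.concentration(matrix)[mask]
            rows.append({
                "day_label": label, "matrix": matrix,
                "auc24": float(np.trapezoid(conc, t)),
                "cmax": float(conc.max()),
            })
    return pd.DataFrame(rows)


def metabolite_formation_report(simout: SimOutput,
                                windows: dict[str, tuple[float, float]] | None = None
                                ) -> pd.DataFrame:
    """Daily (per window) and total cumulative pathway-resolved metabolite amounts.

    Daily formation is the difference of the cumulative trajectory at the
    window bounds; the row ``total`` reports the cumulative amount at the
    end of the simulation.
    """
    pathways = {
        ("liver", "cyp3a4"): "cum_met_cyp3a4_liv",
        ("liver", "other"): "cum_met_other_liv",
        ("gut", "cyp3a4"): "cum_met_cyp3a4_gut",
        ("gut", "other"): "cum_met_other_gut",
    }
    rows = []
    for (tissue, pathway), key in pathways.items():
        cum = simout.cumulative[key]
        for label, (lo, hi) in (windows or {}).items():
            i_lo = int(np.searchsorted(simout.time, lo - 1e-9))
            i_hi = int(np.searchsorted(simout.time, hi - 1e-9))
            if i_hi >= simout.time.size:
                raise ValueError(f"window [{lo}, {hi}] beyond simulated span")
            rows.append({"day_label": label, "tissue": tissue, "pathway": pathway,
                         "amount_nmol": float(cum[i_hi] - cum[i_lo])})
        rows.append({"day_label": "total", "tissue": tissue, "pathway": pathway,
                     "amount_nmol": float(cum[-1])})
    return pd.DataFrame(rows)


def interaction_ratio_table(test: pd.DataFrame, ref: pd.DataFrame,
                            on: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Elementwise 100 · test/ref on the shared label columns.

    The reference table may carry a single row set (e.g. the steady-state
    reference day); it is then broadcast against every test window.
    """
    value_cols = [c for c in test.columns if test[c].dtype.kind == "f"]
    keys = list(on) if on is not None else [
        c for c in test.columns if c not in value_cols and c != "day_label"]
    ref_small = ref[keys + value_cols].groupby(keys, as_index=False).first() \
        if keys else ref[value_cols].iloc[:1]
    merged = test.merge(ref_small, on=keys, suffixes=("", "_ref")) if keys \
        else test.assign(**{f"{c}_ref": ref_small[c].iloc[0] for c in value_cols})
    out = merged.copy()
    for c in value_cols:
        ref_vals = merged[f"{c}_ref"]
        if (ref_vals == 0).any():
            raise ZeroDivisionError(f"zero reference value in column {c!r}")
        out[f"{c}_pct_of_ref"] = 100.0 * merged[c] / ref_vals
    return out


def sensitivity_coefficients(spec: ScenarioSpec, sub: SubstanceParams,
                             phys: PhysiologyParams,
                             params=("fm_cyp3a4", "ec50", "emax", "ki"),
                             perturbation: float = 0.10,
                             rifp: ddi.Rif2CompParams | None = None,
                             ip: ddi.InductionParams | None = None,
                             **solver_options) -> pd.DataFrame:
    """Normalized local sensitivity of cumulative CYP3A4 metabolites at 5 weeks.

    coefficient = (ΔA/A0) / (Δp/p0) for each parameter, perturbation
    direction and tissue (liver, gut).
    """
    ip = ip or ddi.canonical_induction_params()
    solver_options.setdefault("rtol", 1e-8)
    solver_options.setdefault("atol", 1e-10)

    def outputs(sub_i, ip_i):
        sim = run_scenario(spec, sub_i, phys, rifp=rifp, ip=ip_i, **solver_options)
        return {"liver": float(sim.cumulative["cum_met_cyp3a4_liv"][-1]),
                "gut": float(sim.cumulative["cum_met_cyp3a4_gut"][-1])}

    base = outputs(sub, ip)
    rows = []
    for pname in params:
        p0 = getattr(sub, pname) if pname == "fm_cyp3a4" else getattr(ip, pname)
        for direction, sign in (("+", 1.0), ("-", -1.0)):
            p_new = p0 * (1.0 + sign * perturbation)
            if pname == "fm_cyp3a4":
                pert = outputs(sub.with_overrides(fm_cyp3a4=p_new), ip)
            else:
                pert = outputs(sub, ip.with_overrides(**{pname: p_new}))
            for tissue in ("liver", "gut"):
                delta_rel = (pert[tissue] - base[tissue]) / base[tissue]
                rows.append({"parameter": pname, "direction": direction,
                             "tissue": tissue,
                             "coefficient": delta_rel / (sign * perturbation)})
    return pd.DataFrame(rows)
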