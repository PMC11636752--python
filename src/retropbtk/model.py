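"""Whole-body PBTK model of retrorsine with an extended-clearance liver.

Flow-limited tissue compartments are linked by blood-flow-scaled plasma
transport; the liver is split into a lumped vascular/interstitial space and
a cellular space. Sinusoidal influx into the hepatocyte combines active
(carrier-mediated) uptake on unbound plasma concentration with passive
diffusion; efflux is passive only; metabolism acts on the unbound cellular
concentration. The gut absorbs from the lumen at a first-order rate with a
fraction absorbed, metabolizes in its small-intestinal cellular fraction,
and drains into the portal vein. Renal elimination is glomerular filtration
of unbound drug from venous plasma.

Metabolism in liver and gut is split into a CYP3A4 pathway — scaled by the
relative enzyme level and competitively inhibited by intracellular
rifampicin — and a non-CYP3A4 pathway that is neither induced nor inhibited.
The rifampicin disposition and CYP3A4 turnover states are integrated jointly
with the victim states; without a rifampicin regimen they stay identically
at zero drug / baseline enzyme, so the coupled system reduces exactly to the
victim-only model.

Units: amounts nmol (retrorsine) and µmol (rifampicin), time h, volumes L,
concentrations nmol/L (retrorsine) and µmol/L (rifampicin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .ddi import InductionParams, Rif2CompParams, rifampicin_2comp_rhs
from .physiology import PhysiologyParams
from .substance import SubstanceParams

__all__ = [
    "DoseRegimen",
    "Interaction",
    "SimOutput",
    "extended_liver_clearance",
    "retrorsine_rhs",
    "simulate",
    "bioavailability_decomposition",
    "biodistribution_report",
]

# retrorsine state indices
I_LUMEN, I_GUT, I_VEN, I_ART, I_LUNG, I_ADI, I_BON, I_MUS, I_SPL, I_KID, \
    I_HEA, I_RES, I_LIV_EXT, I_LIV_CELL = range(14)
I_MET3A4_LIV, I_MET_OTH_LIV, I_MET3A4_GUT, I_MET_OTH_GUT, I_RENAL, I_FECAL = range(14, 20)
# rifampicin (µmol) and relative enzyme states
I_RIF = 20  # depot/central/peripheral for liver then gut
I_E_LIV, I_E_GUT = 26, 27
N_STATE = 28

AMOUNT_NAMES = {
    I_LUMEN: "gut_lumen", I_GUT: "gut", I_VEN: "venous_plasma",
    I_ART: "arterial_plasma", I_LUNG: "lung", I_ADI: "adipose", I_BON: "bone",
    I_MUS: "muscle", I_SPL: "spleen", I_KID: "kidney", I_HEA: "heart",
    I_RES: "rest", I_LIV_EXT: "liver_extracellular", I_LIV_CELL: "liver_cellular",
}
CUM_NAMES = {
    I_MET3A4_LIV: "cum_met_cyp3a4_liv", I_MET_OTH_LIV: "cum_met_other_liv",
    I_MET3A4_GUT: "cum_met_cyp3a4_gut", I_MET_OTH_GUT: "cum_met_other_gut",
    I_RENAL: "cum_renal", I_FECAL: "cum_fecal",
}


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated bolus doses of one compound.

    Retrorsine doses are nmol into the gut lumen (or venous plasma for the
    intravenous reference route); rifampicin doses are mg, routed to the
    per-tissue depots of its disposition model.
    """

    compound: str  # "retrorsine" | "rifampicin"
    dose_amount: float
    dose_times: tuple[float, ...]
    route: str = "oral"

    def __post_init__(self) -> None:
        if self.compound not in ("retrorsine", "rifampicin"):
            raise ValueError(f"unknown compound {self.compound!r}")
        if self.route not in ("oral", "iv"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.dose_amount <= 0:
            raise ValueError("dose_amount must be positive")
        times = tuple(self.dose_times)
        if any(t < 0 for t in times):
            raise ValueError("dose times must be non-negative")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("dose_times must be non-decreasing")
        object.__setattr__(self, "dose_times", times)


@dataclass(frozen=True)
class Interaction:
    """Bundle of the perpetrator model coupled into the simulation."""

    rifampicin: Rif2CompParams
    induction: InductionParams
    regimen: DoseRegimen | None = None


@dataclass
class SimOutput:
    """Dense simulation output on a uniform time grid."""

    time: np.ndarray  # h
    states: np.ndarray  # (n_state, n_time)
    phys: PhysiologyParams
    interaction: Interaction | None = None
    amounts: dict[str, np.ndarray] = field(init=False)
    cumulative: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        self.amounts = {n: self.states[i] for i, n in AMOUNT_NAMES.items()}
        self.cumulative = {n: self.states[i] for i, n in CUM_NAMES.items()}

    @property
    def enzyme_level_liv(self) -> np.ndarray:
        return self.states[I_E_LIV]

    @property
    def enzyme_level_gut(self) -> np.ndarray:
        return self.states[I_E_GUT]

    def rifampicin_conc(self, tissue: str) -> np.ndarray:
        """Intracellular rifampicin concentration (µM)."""
        if self.interaction is None:
            return np.zeros_like(self.time)
        off = 0 if tissue == "liver" else 3
        v = self.interaction.rifampicin.tissue(tissue).central_volume
        return self.states[I_RIF + off + 1] / v

    def concentration(self, matrix: str) -> np.ndarray:
        """Concentration trajectory (nmol/L) in a reporting matrix."""
        p = self.phys
        if matrix == "plasma":
            return self.states[I_VEN] / p.volume_venous_plasma
        if matrix == "liver":
            return self.states[I_LIV_CELL] / p.volume_liver_cellular
        if matrix == "gut":
            return self.states[I_GUT] / p.tissue_volumes["gut"]
        raise KeyError(f"unknown matrix {matrix!r}; use plasma, liver or gut")

    def body_amount(self) -> np.ndarray:
        """Total drug in the body including the unabsorbed lumen content (nmol)."""
        return self.states[:I_MET3A4_LIV].sum(axis=0)

    def eliminated(self) -> np.ndarray:
        """Total eliminated via all routes including fecal loss (nmol)."""
        return self.states[I_MET3A4_LIV:I_FECAL + 1].sum(axis=0)


class _Compiled:
    """Whole-organ parameters pre-converted to L/h and nmol."""

    __slots__ = (
        "q", "kv", "co", "v_ven", "v_gut", "k_gut", "q_gut", "q_spl", "k_spl",
        "q_ha", "q_liv", "v_ext", "v_cell", "fu_p", "fu_c", "influx", "efflux",
        "vmax_liv", "km_liv", "vmax_gut", "km_gut", "fm", "cl_renal", "k_a",
        "f_a", "rif_liver", "rif_gut", "ind",
    )

    def __init__(self, sub: SubstanceParams, phys: PhysiologyParams,
                 interaction: Interaction | None):
        mlmin_to_lh = 60.0 / 1000.0
        q, v, k = phys.blood_flows, phys.tissue_volumes, sub.k_tis
        # flow-limited tissues drained into venous plasma, plus lung
        order = ["lung", "adipose", "bone", "muscle", "kidney", "heart", "rest"]
        self.q = np.array([q[t] for t in order])
        self.kv = np.array([k[t] * v[t] for t in order])
        self.co = phys.cardiac_output
        self.v_ven = phys.volume_venous_plasma
        self.v_gut = v["gut"]
        self.k_gut = k["gut"]
        self.q_gut = q["gut"]
        self.q_spl = q["spleen"]
        self.k_spl = k["spleen"] * v["spleen"]
        self.q_ha = q["liver_artery"]
        self.q_liv = phys.liver_blood_flow
        self.v_ext = phys.volume_liver_extracellular
        self.v_cell = phys.volume_liver_cellular
        self.fu_p = sub.fu_plasma
        self.fu_c = sub.fu_liver_cell
        ps = sub.ps_diff * phys.liver_mass * mlmin_to_lh
        act = sub.cl_act_in * phys.liver_mass * mlmin_to_lh
        self.influx = self.fu_p * (act + ps)  # L/h on extracellular conc
        self.efflux = self.fu_c * ps  # L/h on cellular conc
        self.vmax_liv = sub.vmax_liv * phys.liver_mass * 60.0  # nmol/h
        self.km_liv = sub.km_liv * 1000.0  # nmol/L
        gut_cell_g = phys.gut_cellular_volume * 1000.0  # g at unit density
        self.vmax_gut = sub.vmax_gut * gut_cell_g * 60.0  # nmol/h
        self.km_gut = sub.km_gut * 1000.0  # nmol/L
        self.fm = sub.fm_cyp3a4
        self.cl_renal = sub.cl_renal * phys.body_weight * mlmin_to_lh  # L/h
        self.k_a = sub.k_a
        self.f_a = sub.f_a
        if interaction is not None:
            self.rif_liver = interaction.rifampicin.liver
            self.rif_gut = interaction.rifampicin.gut
            self.ind = interaction.induction
        else:
            self.rif_liver = self.rif_gut = None
            self.ind = InductionParams()


def retrorsine_rhs(t: float, y, sub: SubstanceParams, phys: PhysiologyParams,
                   enzyme_level=None, rif_conc=None,
                   interaction: Interaction | None = None) -> np.ndarray:
    """Full-system derivatives at state ``y`` (validating wrapper).

    ``enzyme_level`` and ``rif_conc`` may override the corresponding state
    entries (maps with keys 'liver' and 'gut'), which is convenient for
    interrogating the victim kinetics at a frozen interaction state.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (N_STATE,):
        if y.size > N_STATE:
            raise ValueError(f"state has {y.size} entries, expected ≤ {N_STATE}")
        padded = np.zeros(N_STATE)
        padded[I_E_LIV] = padded[I_E_GUT] = 1.0
        padded[: y.size] = y[: min(y.size, I_E_LIV)] if y.size <= I_E_LIV else y
        y = padded
    if np.any(~np.isfinite(y)):
        raise ValueError("state contains non-finite entries")
    if np.any(y[:I_MET3A4_LIV] < -1e-9):
        raise ValueError("amounts must be non-negative")
    c = _Compiled(sub, phys, interaction)
    if enzyme_level is not None:
        y = y.copy()
        y[I_E_LIV] = enzyme_level.get("liver", 1.0)
        y[I_E_GUT] = enzyme_level.get("gut", 1.0)
    if rif_conc is not None and interaction is not None:
        y = y.copy()
        y[I_RIF + 1] = rif_conc.get("liver", 0.0) * c.rif_liver.central_volume
        y[I_RIF + 4] = rif_conc.get("gut", 0.0) * c.rif_gut.central_volume
    return _full_rhs(t, y, c, phys)


def _full_rhs(t: float, y: np.ndarray, c: _Compiled,
              phys: PhysiologyParams) -> np.ndarray:
    dy = np.zeros(N_STATE)
    conc_art = y[I_ART] / phys.volume_arterial_plasma
    conc_ven = y[I_VEN] / c.v_ven

    # lung in series between venous and arterial plasma
    tis_idx = (I_LUNG, I_ADI, I_BON, I_MUS, I_KID, I_HEA, I_RES)
    conc_tis = y[list(tis_idx)] / c.kv  # venous-equilibrated concentration
    dy[I_LUNG] = c.co * (conc_ven - conc_tis[0])
    dy[I_ART] = c.co * conc_tis[0] - c.co * conc_art
    # systemic flow-limited tissues (lung handled above)
    returns = 0.0
    for j, idx in enumerate(tis_idx[1:], start=1):
        qj = c.q[j]
        dy[idx] = qj * (conc_art - conc_tis[j])
        returns += qj * conc_tis[j]

    # rifampicin and enzyme turnover
    rif_c_liv = rif_c_gut = 0.0
    if c.rif_liver is not None:
        dy[I_RIF:I_RIF + 3] = rifampicin_2comp_rhs(t, y[I_RIF:I_RIF + 3], c.rif_liver)
        dy[I_RIF + 3:I_RIF + 6] = rifampicin_2comp_rhs(t, y[I_RIF + 3:I_RIF + 6], c.rif_gut)
        rif_c_liv = max(y[I_RIF + 1], 0.0) / c.rif_liver.central_volume
        rif_c_gut = max(y[I_RIF + 4], 0.0) / c.rif_gut.central_volume
    ind = c.ind
    e_liv, e_gut = y[I_E_LIV], y[I_E_GUT]
    f_ind_liv = ind.emax * rif_c_liv / (ind.ec50 + rif_c_liv)
    f_ind_gut = ind.emax * rif_c_gut / (ind.ec50 + rif_c_gut)
    dy[I_E_LIV] = ind.k_deg_liv * (ind.baseline_relative + f_ind_liv - e_liv)
    dy[I_E_GUT] = ind.k_deg_gut * (ind.baseline_relative + f_ind_gut - e_gut)

    # gut lumen: first-order emptying, fraction f_a absorbed into gut tissue
    absorbed = c.k_a * c.f_a * max(y[I_LUMEN], 0.0)
    dy[I_LUMEN] = -c.k_a * y[I_LUMEN]
    dy[I_FECAL] = c.k_a * (1.0 - c.f_a) * max(y[I_LUMEN], 0.0)

    # gut tissue: flow, absorption, metabolism in the SI cellular space
    conc_gut = y[I_GUT] / c.v_gut
    s_gut = max(conc_gut, 0.0)
    inhib_gut = 1.0 + rif_c_gut / ind.ki
    v3a4_gut = c.fm * c.vmax_gut * e_gut * s_gut / (c.km_gut * inhib_gut + s_gut)
    voth_gut = (1.0 - c.fm) * c.vmax_gut * s_gut / (c.km_gut + s_gut)
    gut_out = c.q_gut * conc_gut / c.k_gut
    dy[I_GUT] = c.q_gut * conc_art - gut_out + absorbed - v3a4_gut - voth_gut
    dy[I_MET3A4_GUT] = v3a4_gut
    dy[I_MET_OTH_GUT] = voth_gut

    # splanchnic (portal-drained) tissue
    conc_spl = y[I_SPL] / c.k_spl
    dy[I_SPL] = c.q_spl * (conc_art - conc_spl)

    # liver: extracellular exchange and cellular metabolism
    conc_ext = y[I_LIV_EXT] / c.v_ext
    conc_cell = y[I_LIV_CELL] / c.v_cell
    uptake = c.influx * conc_ext
    backflux = c.efflux * conc_cell
    s_liv = c.fu_c * max(conc_cell, 0.0)
    inhib_liv = 1.0 + rif_c_liv / ind.ki
    v3a4_liv = c.fm * c.vmax_liv * e_liv * s_liv / (c.km_liv * inhib_liv + s_liv)
    voth_liv = (1.0 - c.fm) * c.vmax_liv * s_liv / (c.km_liv + s_liv)
    dy[I_LIV_EXT] = (c.q_ha * conc_art + gut_out + c.q_spl * conc_spl
                     - c.q_liv * conc_ext - uptake + backflux)
    dy[I_LIV_CELL] = uptake - backflux - v3a4_liv - voth_liv
    dy[I_MET3A4_LIV] = v3a4_liv
    dy[I_MET_OTH_LIV] = voth_liv

    # venous plasma: tissue returns, hepatic outflow, renal filtration
    renal = c.cl_renal * conc_ven
    dy[I_VEN] = returns + c.q_liv * conc_ext - c.co * conc_ven - renal
    dy[I_RENAL] = renal
    return dy


def extended_liver_clearance(sub: SubstanceParams, phys: PhysiologyParams) -> float:
    """Whole-liver clearance (mL/min/kg body weight) by the extended clearance model.

    Combines hepatic blood flow, unbound active uptake, metabolic, biliary
    and efflux clearances; with efflux and biliary clearance zero this
    reduces to Q·fu·CL_act,in / (Q + fu·CL_act,in) in total-organ units.
    """
    q = phys.liver_blood_flow * 1000.0 / 60.0  # mL/min
    m = phys.liver_mass
    cl_act = sub.cl_act_in * m
    cl_met = sub.vmax_liv / sub.km_liv * m  # (nmol/min/g)/(nmol/mL) * g = mL/min
    cl_bile = sub.cl_bile * m
    cl_ef = sub.cl_act_ef * m
    fu = sub.fu_plasma
    num = q * fu * cl_act * (cl_met + cl_bile)
    den = q * (cl_ef + cl_met + cl_bile) + fu * cl_act * (cl_met + cl_bile)
    if den == 0.0:
        return 0.0
    return num / den / phys.body_weight


def _dose_events(regimens, interaction: Interaction | None):
    events: dict[float, np.ndarray] = {}
    all_regimens = list(regimens)
    if interaction is not None and interaction.regimen is not None:
        all_regimens.append(interaction.regimen)
    for reg in all_regimens:
        for td in reg.dose_times:
            bolus = events.setdefault(float(td), np.zeros(N_STATE))
            if reg.compound == "retrorsine":
                target = I_LUMEN if reg.route == "oral" else I_VEN
                bolus[target] += reg.dose_amount
            else:
                if interaction is None:
                    raise ValueError(
                        "a rifampicin regimen requires an interaction model"
                    )
                dose_umol = reg.dose_amount / 822.94 * 1000.0
                rp = interaction.rifampicin
                bolus[I_RIF] += rp.liver.dose_bioavailable_fraction * dose_umol
                bolus[I_RIF + 3] += rp.gut.dose_bioavailable_fraction * dose_umol
    return dict(sorted(events.items()))


def simulate(regimens, sub: SubstanceParams, phys: PhysiologyParams,
             interaction: Interaction | None = None, t_end: float = 48.0,
             dt_out: float = 0.1, rtol: float = 1e-10, atol: float = 1e-12,
             method: str = "LSODA") -> SimOutput:
    """Multi-dose simulation with event restarts at every dose time.

    Doses are instantaneous additions to the gut lumen (retrorsine, oral),
    venous plasma (retrorsine, iv reference) or the rifampicin depots; the
    integrator restarts at each event. Dense output on a uniform grid of
    spacing ``dt_out`` (≤ 0.1 h recommended for 24-h window metrics).
    """
    events = _dose_events(regimens, interaction)
    if events and max(events) >= t_end:
        raise ValueError("t_end must lie beyond the last dose time")
    c = _Compiled(sub, phys, interaction)
    grid = np.arange(0.0, t_end + dt_out / 2, dt_out)
    grid[-1] = min(grid[-1], t_end)
    y = np.zeros(N_STATE)
    y[I_E_LIV] = y[I_E_GUT] = c.ind.baseline_relative
    out = np.zeros((N_STATE, grid.size))
    boundaries = sorted(set(events) | {0.0, float(t_end)})
    if not events:
        out[:] = y[:, None]
        return SimOutput(time=grid, states=out, phys=phys, interaction=interaction)

    filled = 0
    for seg_start, seg_end in zip(boundaries[:-1], boundaries[1:]):
        if seg_start in events:
            y = y + events[seg_start]
        mask = (grid >= seg_start - 1e-12) & (grid <= seg_end + 1e-12)
        t_eval = grid[mask]
        sol = solve_ivp(lambda t, s: _full_rhs(t, s, c, phys),
                        (seg_start, seg_end), y, method=method,
                        t_eval=t_eval if t_eval.size else None,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed on [{seg_start}, {seg_end}]: {sol.message}"
            )
        if t_eval.size:
            out[:, np.flatnonzero(mask)] = sol.y
            filled += t_eval.size
        y = sol.y[:, -1] if sol.y.shape[1] else y
    return SimOutput(time=grid, states=out, phys=phys, interaction=interaction)


def bioavailability_decomposition(sub: SubstanceParams, phys: PhysiologyParams,
                                  dose_nmol: float = 100.0,
                                  t_end: float = 96.0) -> tuple[float, float, float, float]:
    """Oral bioavailability F and its decomposition F = F_a · F_g · F_h.

    F is measured as the venous-plasma AUC ratio of matched single oral and
    intravenous doses; each AUC is evaluated exactly as cumulative renal
    excretion divided by renal clearance (renal filtration integrates the
    venous concentration within the solver, avoiding quadrature error on the
    intravenous mixing spike). F_h is the single-transit hepatic escape
    fraction of the extended clearance model, and F_g = F / (F_a · F_h) the
    fraction of the absorbed dose escaping gut first-pass metabolism.
    """
    oral = simulate([DoseRegimen("retrorsine", dose_nmol, (0.0,), "oral")],
                    sub, phys, t_end=t_end, dt_out=0.05)
    iv = simulate([DoseRegimen("retrorsine", dose_nmol, (0.0,), "iv")],
                  sub, phys, t_end=t_end, dt_out=0.05)
    auc_oral = oral.cumulative["cum_renal"][-1]
    auc_iv = iv.cumulative["cum_renal"][-1]
    f_total = auc_oral / auc_iv
    cl_liv = extended_liver_clearance(sub, phys) * phys.body_weight * 60.0 / 1000.0
    f_h = 1.0 - cl_liv / phys.liver_blood_flow
    f_a = sub.f_a
    f_g = f_total / (f_a * f_h)
    return f_total, f_a, f_g, f_h


def biodistribution_report(simout: SimOutput, dose_nmol: float,
                           threshold: float = 1e-4) -> dict:
    """Tissue peak fractions of dose and elimination-route shares.

    Route shares (liver metabolism, gut metabolism, renal excretion) are
    evaluated at the first time the amount remaining in the body — including
    unabsorbed lumen content — falls below ``threshold`` of the dose.
    """
    peaks = {name: float(traj.max() / dose_nmol)
             for name, traj in simout.amounts.items()}
    body = simout.body_amount()
    below = np.flatnonzero(body <= threshold * dose_nmol)
    if below.size == 0:
        raise ValueError("simulation too short: body burden never fell below threshold")
    i99 = below[0]
    cum = simout.cumulative
    liv = cum["cum_met_cyp3a4_liv"][i99] + cum["cum_met_other_liv"][i99]
    gut = cum["cum_met_cyp3a4_gut"][i99] + cum["cum_met_other_gut"][i99]
    ren = cum["cum_renal"][i99]
    routed = liv + gut + ren
    return {
        "tissue_peak_fraction": peaks,
        "elimination_time_h": float(simout.time[i99]),
        "route_shares": {
            "liver_metabolism": float(liv / routed),
            "gut_metabolism": float(gut / routed),
            "renal_excretion": float(ren / routed),
        },
    }
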