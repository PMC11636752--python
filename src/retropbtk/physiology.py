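"""Reference-human physiology for the whole-body toxicokinetic model.

The model body is the ICRP standard adult male (73 kg, 35 y). Tissues are
flow-limited except the liver, which is split into a lumped
vascular/interstitial space and a cellular space (extended clearance model).
The gut compartment lumps small and large intestine; only the small-intestinal
cellular fraction ``f_si`` of its volume expresses CYP3A4 and metabolizes the
substrate.

Conventions
-----------
* volumes in L, flows in L/h, masses in g, time in h
* the circulating pool is plasma (venous + arterial) transported with total
  blood-flow magnitudes; tissue partition coefficients are tissue-to-plasma
* portal topology: gut and splanchnic ("spleen", lumping spleen, stomach and
  pancreas) drain into the liver, which additionally receives the hepatic
  artery; everything else drains into venous plasma; lung sits in series
  between venous and arterial plasma
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["PhysiologyParams", "build_reference_human"]

#: tissues drained directly into venous plasma
SYSTEMIC_TISSUES = ("adipose", "bone", "muscle", "kidney", "heart", "rest")
#: tissues drained into the portal vein (towards the liver)
PORTAL_TISSUES = ("gut", "spleen")
#: all flow-limited tissue compartments
FLOW_TISSUES = SYSTEMIC_TISSUES + PORTAL_TISSUES + ("lung",)


@dataclass(frozen=True)
class PhysiologyParams:
    """Anatomy and physiology of the reference human.

    ``blood_flows`` carries one entry per flow-limited tissue plus
    ``liver_artery``; the total hepatic flow is artery + portal drainage.
    """

    body_weight: float = 73.0  # kg
    cardiac_output: float = 390.0  # L/h (6.5 L/min)
    tissue_volumes: dict[str, float] = field(default_factory=dict)  # L
    blood_flows: dict[str, float] = field(default_factory=dict)  # L/h
    liver_mass: float = 1800.0  # g
    volume_liver_extracellular: float = 0.50  # L, lumped vascular/interstitial
    volume_liver_cellular: float = 1.30  # L
    volume_venous_plasma: float = 2.0  # L
    volume_arterial_plasma: float = 1.0  # L
    gfr: float = 6.57  # L/h (1.5 mL/min/kg * 73 kg)
    f_si: float = 0.94  # small-intestinal cellular fraction of gut volume

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if not 0 < self.f_si <= 1:
            raise ValueError("f_si must lie in (0, 1]")
        for name, v in {**self.tissue_volumes, "liver_ext": self.volume_liver_extracellular,
                        "liver_cell": self.volume_liver_cellular,
                        "ven": self.volume_venous_plasma, "art": self.volume_arterial_plasma}.items():
            if v <= 0:
                raise ValueError(f"volume of {name!r} must be positive")
        for name, q in self.blood_flows.items():
            if q <= 0:
                raise ValueError(f"blood flow of {name!r} must be positive")
        if self.tissue_volumes:
            total = sum(self.blood_flows[t] for t in SYSTEMIC_TISSUES + PORTAL_TISSUES)
            total += self.blood_flows["liver_artery"]
            if abs(total - self.cardiac_output) > 0.01 * self.cardiac_output:
                raise ValueError(
                    f"systemic organ flows ({total:.1f} L/h) do not sum to cardiac "
                    f"output ({self.cardiac_output:.1f} L/h) within 1%"
                )

    @property
    def liver_blood_flow(self) -> float:
        """Total hepatic flow: artery plus portal drainage (L/h)."""
        q = self.blood_flows
        return q["liver_artery"] + sum(q[t] for t in PORTAL_TISSUES)

    @property
    def gut_cellular_volume(self) -> float:
        """Small-intestinal cellular volume, the site of gut CYP3A4 (L)."""
        return self.f_si * self.tissue_volumes["gut"]

    def with_overrides(self, **kwargs) -> "PhysiologyParams":
        return replace(self, **kwargs)


def build_reference_human() -> PhysiologyParams:
    """ICRP-based reference adult male of 73 kg.

    Volumes and regional flow fractions follow standard reference-man
    compilations; the liver cellular space (1.30 L), gut tissue volume
    (1.02 L) and the hepatic flow share (25.5% of cardiac output, i.e.
    99.45 L/h with an 1800 g liver) pin the hepatic clearance of the
    substrate at its reported value. ``rest`` lumps brain, skin and the
    remaining perfused mass so that organ flows close the circulation.
    """
    co = 390.0
    volumes = {
        "lung": 0.53,
        "adipose": 17.5,
        "bone": 10.5,
        "muscle": 29.0,
        "spleen": 0.18,
        "kidney": 0.31,
        "heart": 0.33,
        "gut": 1.02,
        "rest": 9.0,
    }
    frac = {
        "adipose": 0.05,
        "bone": 0.05,
        "muscle": 0.17,
        "spleen": 0.05,   # lumps spleen + stomach + pancreas drainage
        "kidney": 0.19,
        "heart": 0.04,
        "gut": 0.14,
        "rest": 0.245,
        "liver_artery": 0.065,
    }
    flows = {k: f * co for k, f in frac.items()}
    flows["lung"] = co
    return PhysiologyParams(tissue_volumes=volumes, blood_flows=flows)
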