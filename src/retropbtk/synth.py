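"""Synthetic raw-data generators emulating the study's measured inputs.

Three designs are emulated so that every pipeline stage can be exercised
without any measured data:

* medium-loss depletion time courses (one temperature condition at a time,
  4 biological × 2 technical replicates),
* microsomal depletion at initial concentrations 1, 15, 50 and 200 µM
  (2 technical replicates), and
* intracellular rifampicin concentration-time profiles in liver and small
  intestine under 600 mg/day oral dosing.

Measurement error is multiplicative lognormal with a default coefficient of
variation of 0.1, reflecting typical LC-MS/MS assay precision; biological
and technical replicates share the same noise model. Every generator is a
pure function of (truth, design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddi import Rif2CompParams, canonical_rifampicin_params, rifampicin_concentration
from .invitro import (EndProductInhibitionParams, MonoexpParams,
                      integrate_end_product_inhibition, monoexponential_depletion)

__all__ = [
    "NoiseSpec",
    "MEDIUM_LOSS_TIMES_H",
    "MICROSOMAL_TIMES_H",
    "gen_medium_loss_dataset",
    "gen_microsomal_dataset",
    "gen_rifampicin_profiles",
]

#: default sampling grids of typical depletion assays (h)
MEDIUM_LOSS_TIMES_H = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 24.0)
MICROSOMAL_TIMES_H = tuple(m / 60.0 for m in (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0))


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative lognormal measurement noise."""

    cv: float = 0.1
    seed: int = 20240325

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.cv == 0:
            return np.asarray(values, dtype=float)
        sigma = np.sqrt(np.log(1.0 + self.cv**2))
        return values * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma,
                                      size=np.shape(values))


def gen_medium_loss_dataset(lambda_rate: float, c0: float,
                            times=MEDIUM_LOSS_TIMES_H, condition: float = 37.0,
                            n_bio: int = 4, n_tech: int = 2,
                            noise: NoiseSpec = NoiseSpec()) -> pd.DataFrame:
    """Replicated monoexponential medium-loss time courses (tidy frame).

    ``condition`` carries the incubation temperature in °C; the dataset has
    ``len(times) * n_bio * n_tech`` rows.
    """
    rng = np.random.default_rng(noise.seed)
    truth = monoexponential_depletion(MonoexpParams(lambda_rate, c0), np.asarray(times))
    rows = []
    for b in range(n_bio):
        for k in range(n_tech):
            obs = noise.apply(truth, rng)
            for t, c in zip(times, obs):
                rows.append({"assay_id": "medium_loss", "condition": condition,
                             "replicate_id": f"bio{b + 1}_tech{k + 1}",
                             "time_h": t, "concentration_uM": c})
    return pd.DataFrame(rows)


def gen_microsomal_dataset(params: EndProductInhibitionParams,
                           c0_list=(1.0, 15.0, 50.0, 200.0),
                           times=MICROSOMAL_TIMES_H, n_tech: int = 2,
                           noise: NoiseSpec = NoiseSpec()) -> pd.DataFrame:
    """Microsomal depletion curves at several initial concentrations.

    ``condition`` carries the initial substrate concentration (µM); curves
    come from numerical integration of the end-product inhibition model.
    """
    rng = np.random.default_rng(noise.seed)
    t_h = np.asarray(times, dtype=float)
    rows = []
    for c0 in c0_list:
        truth = integrate_end_product_inhibition(params, c0, t_h * 60.0)
        for k in range(n_tech):
            obs = noise.apply(truth, rng)
            for t, c in zip(t_h, obs):
                rows.append({"assay_id": "microsomal", "condition": float(c0),
                             "replicate_id": f"tech{k + 1}",
                             "time_h": t, "concentration_uM": c})
    return pd.DataFrame(rows)


def gen_rifampicin_profiles(params: Rif2CompParams | None = None,
                            dose_mg: float = 600.0, n_doses: int = 14,
                            sampling_h: np.ndarray | None = None,
                            noise: NoiseSpec = NoiseSpec()) -> pd.DataFrame:
    """Noisy intracellular rifampicin profiles in liver and small intestine.

    With the canonical parameters the steady-state peaks are ≈140 µmol/L in
    liver and ≈20 µmol/L in gut. ``dose_mg = 0`` yields zero profiles.
    """
    params = params or canonical_rifampicin_params()
    if sampling_h is None:
        last = (n_doses - 1) * 24.0
        # dense sampling over the last dosing interval plus sparse build-up
        # (starts post-dose; a log-error model needs positive observations)
        sampling_h = np.concatenate([
            np.arange(1.0, last, 6.0),
            last + np.array([0.5, 1, 2, 3, 4, 6, 8, 12, 16, 20, 24]),
        ])
    rng = np.random.default_rng(noise.seed)
    dose_times = [24.0 * i for i in range(n_doses)]
    rows = []
    for tissue in ("liver", "gut"):
        if dose_mg == 0:
            conc = np.zeros_like(np.asarray(sampling_h, dtype=float))
        else:
            conc = rifampicin_concentration(params.tissue(tissue), dose_times,
                                            dose_mg, sampling_h)
            conc = noise.apply(conc, rng)
        for t, c in zip(sampling_h, conc):
            rows.append({"tissue": tissue, "time_h": float(t),
                         "concentration_uM": float(c)})
    return pd.DataFrame(rows)
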