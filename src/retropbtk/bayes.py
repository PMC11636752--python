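"""Single-chain adaptive random-walk Metropolis sampling and posterior summaries.

All kinetic parameters handled here are strictly positive, so the sampler
walks in log-parameter space with a diagonal Gaussian proposal whose scale is
adapted toward a target acceptance rate during burn-in only (the retained
half of the chain uses a frozen proposal). Results are reported the way the
fits are tabulated: posterior mode (kernel-density argmax) with equal-tailed
95% credible interval, and Monte-Carlo predictive bands from parameter draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MCMCResult",
    "PosteriorSummary",
    "log_uniform_about",
    "run_metropolis",
    "summarize_posterior",
    "predictive_band",
]

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20240325


def log_uniform_about(center: float, decades: float = 4.0):
    """Weakly informative log-uniform prior spanning ±``decades`` around ``center``."""
    if center <= 0:
        raise ValueError("center of a log-uniform prior must be positive")
    return stats.loguniform(center * 10.0 ** (-decades), center * 10.0 ** decades)


@dataclass(frozen=True)
class MCMCResult:
    """Post-burn-in chain with sampling metadata."""

    chains: np.ndarray  # (n_samples, n_params), natural scale
    log_posterior: np.ndarray  # (n_samples,)
    acceptance_rate: float
    param_names: tuple[str, ...] = ()

    def __len__(self) -> int:
        return self.chains.shape[0]


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter mode and equal-tailed 95% credible interval."""

    mode: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    chains: np.ndarray
    acceptance_rate: float
    param_names: tuple[str, ...] = ()

    def as_table(self):
        import pandas as pd

        names = self.param_names or tuple(f"p{i}" for i in range(self.mode.size))
        return pd.DataFrame(
            {"parameter": names, "mode": self.mode,
             "ci_low": self.ci_low, "ci_high": self.ci_high}
        )

    def format_row(self, i: int, fmt: str = "{:.3g}") -> str:
        """Render one parameter as ``mode[low, high]``."""
        return (fmt.format(self.mode[i]) + "[" + fmt.format(self.ci_low[i])
                + ", " + fmt.format(self.ci_high[i]) + "]")


def run_metropolis(
    log_likelihood,
    priors,
    init,
    n_iter: int = 20_000,
    seed: int = DEFAULT_SEED,
    param_names: tuple[str, ...] = (),
    target_accept: float = 0.30,
    initial_step: float = 0.25,
) -> MCMCResult:
    """Adaptive random-walk Metropolis in log-parameter space.

    Parameters
    ----------
    log_likelihood
        Callable on a parameter vector (natural scale) returning a scalar.
    priors
        One frozen scipy distribution (``.logpdf``) per parameter; supports
        must be positive.
    init
        Starting parameter vector (natural scale, strictly positive).
    n_iter
        Total iterations; the first half is discarded as burn-in.
    seed
        Seed of the single chain; identical seeds give identical chains.
    """
    init = np.asarray(init, dtype=float)
    if n_iter < 2000:
        raise ValueError("n_iter must be at least 2000")
    if np.any(init <= 0):
        raise ValueError("initial parameters must be strictly positive")
    d = init.size
    if len(priors) != d:
        raise ValueError("need one prior per parameter")

    def log_post(theta: np.ndarray) -> float:
        lp = 0.0
        for x, pr in zip(theta, priors):
            lp += pr.logpdf(x)
        if not np.isfinite(lp):
            return -np.inf
        ll = log_likelihood(theta)
        if not np.isfinite(ll):
            return -np.inf
        # Jacobian of the log-transform: sampling density over log(theta)
        return ll + lp + np.sum(np.log(theta))

    rng = np.random.default_rng(seed)
    x = np.log(init)
    lp = log_post(np.exp(x))
    if not np.isfinite(lp):
        raise ValueError(
            "log-posterior is not finite at the initial parameter vector; "
            "check data, priors and the initial guess"
        )

    burn = n_iter // 2
    step = float(initial_step)
    chain = np.empty((n_iter - burn, d))
    logp = np.empty(n_iter - burn)
    n_accept_post = 0
    accept_window = 0
    for it in range(n_iter):
        prop = x + step * rng.standard_normal(d)
        lp_prop = log_post(np.exp(prop))
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accept_window += 1
            if it >= burn:
                n_accept_post += 1
        if it < burn:
            # Robbins-Monro style scale adaptation, frozen after burn-in
            if (it + 1) % 50 == 0:
                rate = accept_window / 50.0
                step *= np.exp((rate - target_accept))
                step = min(max(step, 1e-4), 5.0)
                accept_window = 0
        else:
            chain[it - burn] = np.exp(x)
            logp[it - burn] = lp

    return MCMCResult(
        chains=chain,
        log_posterior=logp,
        acceptance_rate=n_accept_post / (n_iter - burn),
        param_names=tuple(param_names),
    )


def _marginal_mode(samples: np.ndarray) -> float:
    lo, hi = samples.min(), samples.max()
    if hi - lo <= 1e-12 * max(abs(hi), 1.0):
        return float(samples[0])
    kde = stats.gaussian_kde(samples)
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


def summarize_posterior(chains, acceptance_rate: float = np.nan,
                        param_names: tuple[str, ...] = ()) -> PosteriorSummary:
    """Mode (KDE argmax) and equal-tailed 95% interval per parameter."""
    if isinstance(chains, MCMCResult):
        acceptance_rate = chains.acceptance_rate
        param_names = param_names or chains.param_names
        chains = chains.chains
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if chains.shape[0] == 1 and chains.shape[1] > chains.shape[0]:
        chains = chains.T
    if chains.shape[0] < 500:
        raise ValueError("need at least 500 post-burn-in samples to summarize")
    if not np.all(np.isfinite(chains)):
        raise ValueError("chain contains non-finite samples")
    mode = np.array([_marginal_mode(chains[:, j]) for j in range(chains.shape[1])])
    ci_low = np.percentile(chains, 2.5, axis=0)
    ci_high = np.percentile(chains, 97.5, axis=0)
    return PosteriorSummary(mode=mode, ci_low=ci_low, ci_high=ci_high,
                            chains=chains, acceptance_rate=acceptance_rate,
                            param_names=tuple(param_names))


def predictive_band(
    chains,
    model,
    n_draws: int = 1000,
    seed: int = DEFAULT_SEED,
    percentiles: tuple[float, float] = (5.0, 95.0),
):
    """Pointwise median and interpercentile band of ``model`` over chain draws.

    ``model`` maps a parameter vector to a curve (1-d array). Draws on which
    the model fails (exception or non-finite output) are logged and
    resampled; more than 10% failures abort.
    """
    if isinstance(chains, MCMCResult):
        chains = chains.chains
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    n = chains.shape[0]
    if n_draws > n:
        raise ValueError("n_draws must not exceed the chain length")
    rng = np.random.default_rng(seed)
    curves = []
    failures = 0
    max_failures = int(0.10 * n_draws)
    while len(curves) < n_draws:
        theta = chains[rng.integers(n)]
        try:
            y = np.asarray(model(theta), dtype=float)
            if not np.all(np.isfinite(y)):
                raise FloatingPointError("non-finite model output")
        except Exception as exc:  # noqa: BLE001 - resample on any model failure
            failures += 1
            logger.warning("model failed on draw (%s); resampling", exc)
            if failures > max_failures:
                raise RuntimeError(
                    f"more than 10% of predictive draws failed ({failures})"
                ) from exc
            continue
        curves.append(y)
    arr = np.stack(curves)
    median = np.median(arr, axis=0)
    lo = np.percentile(arr, percentiles[0], axis=0)
    hi = np.percentile(arr, percentiles[1], axis=0)
    return median, (lo, hi)
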