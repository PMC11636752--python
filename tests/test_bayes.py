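import numpy as np
import pytest
from scipy import stats

from retropbtk.bayes import (log_uniform_about, predictive_band, run_metropolis,
                             summarize_posterior)
from retropbtk.invitro import fit_medium_loss
from retropbtk.synth import NoiseSpec, gen_medium_loss_dataset


def _gaussian_mean_problem(seed=0, n=50, mu=2.0, sigma=0.3):
    rng = np.random.default_rng(seed)
    y = rng.normal(mu, sigma, n)

    def loglik(theta):
        return float(-0.5 * np.sum(((y - theta[0]) / sigma) ** 2))

    return y, loglik


class TestMetropolis:
    def test_recovers_analytic_posterior_mean(self):
        y, loglik = _gaussian_mean_problem()
        res = run_metropolis(loglik, [log_uniform_about(2.0)], np.array([1.0]),
                             n_iter=20000, seed=11)
        # flat-prior posterior for the mean is N(ybar, sigma^2/n)
        ybar, se = y.mean(), 0.3 / np.sqrt(len(y))
        mcse = res.chains[:, 0].std() / np.sqrt(len(res) / 20)  # crude ESS guess
        assert res.chains[:, 0].mean() == pytest.approx(ybar, abs=3 * max(mcse, se / 5))
        assert res.chains[:, 0].std() == pytest.approx(se, rel=0.25)

    def test_same_seed_bit_identical(self):
        _, loglik = _gaussian_mean_problem()
        a = run_metropolis(loglik, [log_uniform_about(2.0)], np.array([1.0]),
                           n_iter=2000, seed=5)
        b = run_metropolis(loglik, [log_uniform_about(2.0)], np.array([1.0]),
                           n_iter=2000, seed=5)
        assert np.array_equal(a.chains, b.chains)

    def test_sharp_likelihood_collapses_to_optimum(self):
        # vanishing data variance: the chain must concentrate at the optimum
        def loglik(theta):
            return float(-0.5 * ((theta[0] - 5.0) / 1e-4) ** 2)

        res = run_metropolis(loglik, [log_uniform_about(5.0)], np.array([4.0]),
                             n_iter=4000, seed=3)
        assert np.all(np.abs(res.chains[-500:, 0] - 5.0) < 0.01)

    def test_nonfinite_logposterior_at_init_aborts(self):
        with pytest.raises(ValueError, match="not finite"):
            run_metropolis(lambda th: np.nan, [log_uniform_about(1.0)],
                           np.array([1.0]), n_iter=2000, seed=0)

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError):
            run_metropolis(lambda th: 0.0, [log_uniform_about(1.0)],
                           np.array([1.0]), n_iter=100, seed=0)


class TestSummaries:
    def test_standard_normal_chain(self):
        rng = np.random.default_rng(42)
        chain = rng.standard_normal(20000)[:, None]
        s = summarize_posterior(chain)
        assert s.mode[0] == pytest.approx(0.0, abs=0.1)
        assert s.ci_low[0] == pytest.approx(-1.96, abs=0.08)
        assert s.ci_high[0] == pytest.approx(1.96, abs=0.08)

    def test_constant_chain_gives_point_mass(self):
        s = summarize_posterior(np.full((1000, 1), 5.0))
        assert s.mode[0] == 5.0
        assert s.ci_low[0] == s.ci_high[0] == 5.0

    def test_reporting_format(self):
        s = summarize_posterior(np.full((1000, 1), 5.0))
        assert s.format_row(0) == "5[5, 5]"

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError, match="500"):
            summarize_posterior(np.ones((100, 1)))


class TestPredictiveBand:
    def test_constant_model_zero_width(self):
        chain = np.random.default_rng(0).uniform(1, 2, (2000, 1))
        med, (lo, hi) = predictive_band(chain, lambda th: np.full(5, 7.0),
                                        n_draws=1000, seed=1)
        assert np.all(hi - lo == 0.0)
        assert np.all(med == 7.0)

    def test_band_widens_with_time_for_monoexponential(self):
        rng = np.random.default_rng(1)
        chain = rng.lognormal(np.log(0.07), 0.2, (2000, 1))
        t = np.linspace(0, 24, 25)
        _, (lo, hi) = predictive_band(chain, lambda th: np.exp(-th[0] * t),
                                      n_draws=1000, seed=2)
        width = hi - lo
        assert width[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(width[:15]) > 0)

    def test_failing_draws_resampled_up_to_limit(self):
        chain = np.arange(1, 1001, dtype=float)[:, None]

        def model(th):
            if th[0] > 950:  # ~5% failure rate: tolerated
                raise RuntimeError("numerical failure")
            return np.array([th[0]])

        med, _ = predictive_band(chain, model, n_draws=500, seed=3)
        assert np.isfinite(med).all()

        def model_bad(th):  # >10% failures must abort
            if th[0] > 700:
                raise RuntimeError("numerical failure")
            return np.array([th[0]])

        with pytest.raises(RuntimeError, match="10%"):
            predictive_band(chain, model_bad, n_draws=500, seed=3)

    def test_too_many_draws_rejected(self):
        with pytest.raises(ValueError):
            predictive_band(np.ones((100, 1)), lambda th: np.ones(2), n_draws=500)


class TestParameterRecovery:
    def test_medium_loss_rate_recovered_within_10pct(self):
        truth = 0.0696
        df = gen_medium_loss_dataset(truth, 5.0, noise=NoiseSpec(0.1, 123))
        s = fit_medium_loss(df, 37.0, seed=9, n_iter=4000)
        assert s.mode[0] == pytest.approx(truth, rel=0.10)
        assert s.ci_low[0] <= truth <= s.ci_high[0]

    def test_credible_interval_coverage(self):
        """Equal-tailed 95% intervals cover the true rate at the nominal level.

        Checked at reduced replication (60 repeats) with a binomial bound:
        P[X < 52 | p=0.95] < 0.3%.
        """
        truth, hits, n_rep = 0.0696, 0, 60
        for rep in range(n_rep):
            df = gen_medium_loss_dataset(truth, 5.0, noise=NoiseSpec(0.1, 1000 + rep))
            s = fit_medium_loss(df, 37.0, seed=2000 + rep, n_iter=2000)
            hits += s.ci_low[0] <= truth <= s.ci_high[0]
        assert hits >= 52

    def test_loguniform_prior_support(self):
        pr = log_uniform_about(1.0, decades=4)
        assert np.isfinite(pr.logpdf(1e-3))
        assert pr.logpdf(1e5) == -np.inf
        with pytest.raises(ValueError):
            log_uniform_about(-1.0)
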