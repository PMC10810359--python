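"""Bayesian Poisson regression: posterior, sampler, diagnostics, DIC."""

import math

import numpy as np
import pandas as pd
import pytest

import fertcount as fc
from fertcount.bayes import diagnostics, poisson_loglik


@pytest.fixture(scope="module")
def poisson_fixture():
    rng = np.random.default_rng(31)
    n = 1000
    X = pd.DataFrame(
        {
            "Intercept": np.ones(n),
            "x1": rng.normal(size=n),
            "x2": rng.binomial(1, 0.5, n).astype(float),
        }
    )
    y = rng.poisson(np.exp(X.to_numpy() @ [0.3, 0.2, -0.3]))
    return X, y


@pytest.fixture(scope="module")
def posterior(poisson_fixture):
    X, y = poisson_fixture
    return fc.sample_posterior(X, y, config=fc.MCMCConfig(seed=77)), X, y


class TestLogPosterior:
    def test_two_observation_hand_sum(self):
        X = np.array([[1.0], [1.0]])
        y = np.array([0.0, 2.0])
        cfg = fc.MCMCConfig(prior_precision=1e-3)
        # beta=0 -> mu=1: loglik = (0 - 1 - log 0!) + (0 - 1 - log 2!)
        loglik = -2.0 - math.log(2.0)
        prior = -0.5 * math.log(2 * math.pi) - math.log(cfg.prior_sd)
        got = fc.log_posterior(np.zeros(1), X, y, None, cfg)
        assert got == pytest.approx(loglik + prior, abs=1e-10)

    def test_flat_prior_limit_differs_from_loglik_by_constant(self):
        X = np.array([[1.0], [1.0], [1.0]])
        y = np.array([1.0, 2.0, 0.0])
        cfg = fc.MCMCConfig(prior_precision=1e-12)
        deltas = [
            fc.log_posterior(np.array([b]), X, y, None, cfg)
            - poisson_loglik(np.array([b]), X, y)
            for b in (-1.0, 0.0, 1.0)
        ]
        assert max(deltas) - min(deltas) < 1e-9

    def test_stronger_prior_penalizes_nonzero_beta(self):
        """The beta-dependent prior penalty lp(beta) - lp(0) shrinks with
        precision (the density's normalizing constant is beta-free)."""
        X = np.array([[1.0], [1.0]])
        y = np.array([1.0, 1.0])
        beta = np.array([0.7])
        zero = np.array([0.0])
        ll_beta = poisson_loglik(beta, X, y)
        ll_zero = poisson_loglik(zero, X, y)

        def penalty(cfg):
            return (fc.log_posterior(beta, X, y, None, cfg) - ll_beta) - (
                fc.log_posterior(zero, X, y, None, cfg) - ll_zero
            )

        weak = penalty(fc.MCMCConfig(prior_precision=1e-3))
        strong = penalty(fc.MCMCConfig(prior_precision=10.0))
        assert strong < weak < 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fc.log_posterior(np.zeros(2), np.ones((3, 1)), np.ones(3), None, fc.MCMCConfig())


class TestSampler:
    def test_same_seed_bit_identical(self, poisson_fixture):
        X, y = poisson_fixture
        cfg = fc.MCMCConfig(seed=5, n_iter=200, burn_in=50)
        a = fc.sample_posterior(X, y, config=cfg)
        b = fc.sample_posterior(X, y, config=cfg)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.acceptance_rate, b.acceptance_rate)

    def test_kept_draw_count_identity(self, poisson_fixture):
        X, y = poisson_fixture
        cfg = fc.MCMCConfig(n_chains=2, n_iter=300, burn_in=100, thin=4, seed=1)
        draws = fc.sample_posterior(X, y, config=cfg)
        assert draws.draws.shape == (2, (300 - 100) // 4, X.shape[1])
        assert draws.n_kept == 2 * 50

    def test_acceptance_rate_in_working_band(self, posterior):
        draws, _, _ = posterior
        assert np.all(draws.acceptance_rate > 0.1)
        assert np.all(draws.acceptance_rate < 0.6)

    def test_posterior_means_near_mle_under_vague_prior(self, posterior):
        draws, X, y = posterior
        mle = fc.fit_poisson(X, y)
        mean = draws.flat().mean(axis=0)
        sd = draws.flat().std(axis=0)
        assert np.all(np.abs(mean - mle.beta.to_numpy()) < 2 * sd)

    def test_recovers_generating_coefficients(self, posterior):
        draws, X, y = posterior
        truth = np.array([0.3, 0.2, -0.3])
        mean = draws.flat().mean(axis=0)
        sd = draws.flat().std(axis=0)
        assert np.all(np.abs(mean - truth) < 3 * sd)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            fc.MCMCConfig(burn_in=1000, n_iter=1000)


class TestAutocorrelation:
    def test_lag_zero_is_one(self):
        assert fc.autocorrelation(np.random.default_rng(0).normal(size=50), 0) == 1.0

    def test_alternating_sequence_lag_one(self):
        x = np.tile([1.0, -1.0], 25)
        assert fc.autocorrelation(x, 1) == pytest.approx(-1.0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=10)
        for lag in (1, 2, 3):
            expected = np.corrcoef(x[:-lag], x[lag:])[0, 1]
            assert fc.autocorrelation(x, lag) == pytest.approx(expected, abs=1e-12)

    def test_constant_chain_flagged_nan(self):
        assert math.isnan(fc.autocorrelation(np.ones(20), 1))


class TestEffectiveSampleSize:
    def test_iid_draws_near_nominal(self):
        x = np.random.default_rng(2).standard_normal(1000)
        assert abs(fc.effective_sample_size(x) - 1000) / 1000 < 0.15

    def test_ar1_closed_form(self):
        from scipy.signal import lfilter

        phi, n = 0.9, 100_000
        rng = np.random.default_rng(1)
        x = lfilter([1.0], [1.0, -phi], rng.standard_normal(n))
        expected = n * (1 - phi) / (1 + phi)
        assert abs(fc.effective_sample_size(x) - expected) / expected < 0.25

    def test_duplicated_chain_bounded_by_twice_single(self):
        x = np.random.default_rng(3).standard_normal(500)
        single = fc.effective_sample_size(x)
        double = fc.effective_sample_size(np.stack([x, x]))
        assert double <= 2 * single + 1e-9

    def test_constant_chains_rejected(self):
        with pytest.raises(ValueError):
            fc.effective_sample_size(np.ones(100))


class TestDic:
    def test_degenerate_posterior_has_zero_penalty(self, poisson_fixture):
        X, y = poisson_fixture
        beta = np.array([0.3, 0.2, -0.3])
        d_bar, penalty, d_pen = fc.dic(np.tile(beta, (5, 1)), X, y)
        assert penalty == pytest.approx(0.0, abs=1e-8)
        assert d_pen == pytest.approx(d_bar)

    def test_three_draw_toy_against_hand_oracle(self):
        X = np.array([[1.0], [1.0]])
        y = np.array([1.0, 0.0])
        draws = np.array([[0.0], [0.5], [-0.5]])
        devs = [-2 * poisson_loglik(b, X, y) for b in draws]
        d_bar = sum(devs) / 3
        pd_ = d_bar - (-2 * poisson_loglik(draws.mean(axis=0), X, y))
        got = fc.dic(draws, X, y)
        assert got[0] == pytest.approx(d_bar, abs=1e-10)
        assert got[1] == pytest.approx(pd_, abs=1e-10)
        assert got[2] == pytest.approx(d_bar + pd_, abs=1e-10)

    def test_reported_triple_additive(self, posterior):
        draws, X, y = posterior
        d_bar, penalty, d_pen = fc.dic(draws, X, y)
        assert d_pen == pytest.approx(d_bar + penalty)
        assert penalty > 0  # spread-out posterior has positive effective parameters


class TestResultsObject:
    def test_summary_and_diagnostics(self, poisson_fixture):
        X, y = poisson_fixture
        res = fc.BayesianPoissonModel(y, X).fit(fc.MCMCConfig(seed=4, n_iter=300))
        summ = res.summary()
        assert list(summ.columns) == ["mean", "sd", "ess"]
        assert list(summ.index) == list(X.columns)
        assert (summ["ess"] <= res.draws.n_kept).all()
        d = res.diagnostics
        assert d.penalized_deviance == pytest.approx(d.mean_deviance + d.penalty)
        assert d.autocorr.iloc[0].tolist() == pytest.approx([1.0] * X.shape[1])

    def test_plots_written(self, tmp_path, poisson_fixture):
        X, y = poisson_fixture
        cfg = fc.MCMCConfig(seed=4, n_iter=150, burn_in=50, n_chains=2)
        draws = fc.sample_posterior(X, y, config=cfg)
        from fertcount.bayes import plot_autocorrelation, plot_density, plot_trace

        plot_trace(draws, tmp_path / "t.png")
        plot_density(draws, tmp_path / "d.png")
        plot_autocorrelation(draws, tmp_path / "a.png")
        for name in ("t.png", "d.png", "a.png"):
            assert (tmp_path / name).stat().st_size > 0
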