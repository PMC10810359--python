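"""Count-model likelihoods, ML fitting, nesting and comparison table."""

import math

import numpy as np
import pandas as pd
import pytest

from scipy.special import expit

import fertcount as fc


def newton_poisson(X, y, offset=None, tol=1e-12):
    """Independent dense Newton oracle for the Poisson MLE."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    off = np.zeros(len(y)) if offset is None else np.asarray(offset, float)
    beta = np.zeros(X.shape[1])
    for _ in range(200):
        mu = np.exp(off + X @ beta)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


class TestNegLogLikelihood:
    def test_poisson_single_zero_observation(self):
        # y=0, mu=1: -log P = -log e^{-1} = 1
        nll = fc.neg_log_likelihood("poisson", [0.0], [[1.0]], [0])
        assert nll == pytest.approx(1.0, abs=1e-12)

    def test_zip_mixture_pmf_at_zero(self):
        # theta=0.2, mu=1: -log(0.2 + 0.8 e^{-1}) = 0.70461
        gamma = [math.log(0.2 / 0.8)]
        nll = fc.neg_log_likelihood("zip", [0.0], [[1.0]], [0], gamma=gamma)
        assert nll == pytest.approx(-math.log(0.2 + 0.8 * math.exp(-1)), abs=1e-10)
        assert nll == pytest.approx(0.70461, abs=1e-5)

    def test_zip_with_zero_inflation_equals_poisson(self, toy_design, zip_counts):
        y, _, _ = zip_counts
        beta = np.array([0.1, 0.2, -0.3])
        pois = fc.neg_log_likelihood("poisson", beta, toy_design, y)
        zip_ = fc.neg_log_likelihood(
            "zip", beta, toy_design, y, gamma=np.array([-40.0, 0.0, 0.0])
        )
        assert zip_ == pytest.approx(pois, rel=1e-12)

    def test_negbin_matches_statsmodels_loglik(self, toy_design, zip_counts):
        from statsmodels.discrete.discrete_model import NegativeBinomial

        y, _, _ = zip_counts
        beta, alpha = np.array([0.1, 0.2, -0.3]), 0.5
        ours = -fc.neg_log_likelihood("negbin", beta, toy_design, y, r=1 / alpha)
        # statsmodels carries ln(alpha) as the auxiliary loglike parameter
        theirs = NegativeBinomial(y, toy_design, loglike_method="nb2").loglike(
            np.r_[beta, np.log(alpha)]
        )
        assert ours == pytest.approx(theirs, rel=1e-10)

    def test_dimension_and_domain_errors(self):
        with pytest.raises(ValueError):
            fc.neg_log_likelihood("poisson", [0.0, 1.0], [[1.0]], [0])
        with pytest.raises(ValueError):
            fc.neg_log_likelihood("poisson", [0.0], [[1.0]], [-1])
        with pytest.raises(ValueError):
            fc.neg_log_likelihood("zip", [0.0], [[1.0]], [0])  # gamma missing


class TestZipDistribution:
    @pytest.mark.parametrize(
        "mu,theta,expected",
        [(2.0, 0.0, (2.0, 2.0)), (2.0, 1.0, (0.0, 0.0)), (2.0, 0.5, (1.0, 2.0))],
    )
    def test_moment_formulas(self, mu, theta, expected):
        assert fc.zip_moments(mu, theta) == pytest.approx(expected)

    def test_theta_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            fc.zip_moments(1.0, 1.2)

    @pytest.mark.parametrize("mu,theta", [(0.5, 0.1), (2.0, 0.5), (8.0, 0.9)])
    def test_pmf_normalizes(self, mu, theta):
        y = np.arange(0, 200)
        total = fc.zip_pmf(y, mu, theta).sum()
        assert abs(total - 1.0) < 1e-10

    def test_moments_match_monte_carlo(self):
        rng = np.random.default_rng(5)
        mu, theta = 1.8, 0.35
        draws = np.where(rng.random(200_000) < theta, 0, rng.poisson(mu, 200_000))
        mean, var = fc.zip_moments(mu, theta)
        assert draws.mean() == pytest.approx(mean, abs=0.02)
        assert draws.var() == pytest.approx(var, rel=0.03)


class TestFitPoisson:
    def test_intercept_only_closed_form(self):
        X = pd.DataFrame({"Intercept": np.ones(30)})
        fit = fc.fit_poisson(X, np.full(30, 3))
        assert fit.beta["Intercept"] == pytest.approx(math.log(3), abs=1e-8)

    def test_intercept_with_offset_is_rate_mle(self):
        rng = np.random.default_rng(0)
        E = rng.uniform(0.5, 3.0, 50)
        y = rng.poisson(1.4 * E)
        X = pd.DataFrame({"Intercept": np.ones(50)})
        fit = fc.fit_poisson(X, y, offset=np.log(E))
        assert fit.beta["Intercept"] == pytest.approx(math.log(y.sum() / E.sum()), abs=1e-8)

    def test_matches_dense_newton_oracle(self):
        rng = np.random.default_rng(1)
        X = np.c_[np.ones(20), rng.normal(size=20), rng.binomial(1, 0.5, 20)]
        off = np.log(rng.uniform(0.5, 2.0, 20))
        y = rng.poisson(np.exp(off + X @ [0.2, 0.3, -0.5]))
        fit = fc.fit_poisson(X, y, offset=off)
        np.testing.assert_allclose(fit.beta.to_numpy(), newton_poisson(X, y, off), atol=1e-6)

    def test_rank_deficiency_rejected(self):
        X = np.c_[np.ones(10), np.ones(10)]
        with pytest.raises(ValueError):
            fc.fit_poisson(X, np.ones(10, dtype=int))


class TestFitNegbin:
    @pytest.fixture(scope="class")
    def nb_data(self, toy_design):
        rng = np.random.default_rng(11)
        beta, r = np.array([0.3, 0.25, -0.4]), 2.0
        mu = np.exp(toy_design.to_numpy() @ beta)
        y = rng.negative_binomial(r, r / (r + mu))
        return y, beta, r

    def test_parameter_recovery(self, toy_design, nb_data):
        y, beta, r = nb_data
        fit = fc.fit_negbin(toy_design, y)
        assert abs(fit.r - r) / r < 0.2
        for name, true in zip(toy_design.columns, beta):
            assert abs(fit.beta[name] - true) < 3 * fit.se_beta[name]

    def test_no_overdispersion_hits_dispersion_cap(self):
        # variance < mean: the dispersion MLE sits at the Poisson boundary
        X = pd.DataFrame({"Intercept": np.ones(1000)})
        y = np.tile([2, 3], 500)
        fit = fc.fit_negbin(X, y)
        assert fit.r == pytest.approx(1e6)
        assert "r_cap" in fit.boundary_flags
        pois = fc.fit_poisson(X, y)
        assert fit.loglik == pytest.approx(pois.loglik, abs=1e-2)
        np.testing.assert_allclose(fit.beta, pois.beta, atol=1e-8)

    def test_loglik_dominates_poisson(self, toy_design, nb_data):
        y, _, _ = nb_data
        assert fc.fit_negbin(toy_design, y).loglik >= fc.fit_poisson(toy_design, y).loglik


class TestFitZip:
    def test_parameter_recovery_within_three_se(self, toy_design):
        rng = np.random.default_rng(13)
        n = 5000
        X = pd.concat([toy_design] * 3, ignore_index=True).iloc[:n]
        beta = np.array([0.2, 0.3, -0.4])
        gamma = np.array([-1.0, 0.5, 0.3])
        A = X.to_numpy()
        y = np.where(
            rng.random(n) < expit(A @ gamma), 0, rng.poisson(np.exp(A @ beta))
        )
        fit = fc.fit_zip(X, y)
        for name, true in zip(X.columns, beta):
            assert abs(fit.beta[name] - true) < 3 * fit.se_beta[name]
        for name, true in zip(X.columns, gamma):
            assert abs(fit.gamma[name] - true) < 3 * fit.se_gamma[name]

    def test_loglik_dominates_poisson(self, toy_design, zip_counts):
        y, _, _ = zip_counts
        assert fc.fit_zip(toy_design, y).loglik >= fc.fit_poisson(toy_design, y).loglik

    def test_no_zeros_pins_theta_at_floor(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame({"Intercept": np.ones(300)})
        y = 1 + rng.poisson(2.0, 300)
        fit = fc.fit_zip(X, y)
        assert "theta_zero" in fit.boundary_flags
        assert expit(fit.gamma["Intercept"]) <= 1e-6


class TestFitZinb:
    def test_theta_zero_data_matches_negbin(self, toy_design):
        rng = np.random.default_rng(15)
        r = 2.0
        mu = np.exp(toy_design.to_numpy() @ [0.3, 0.25, -0.4])
        y = rng.negative_binomial(r, r / (r + mu))
        zinb = fc.fit_zinb(toy_design, y)
        nb = fc.fit_negbin(toy_design, y)
        assert zinb.loglik >= nb.loglik - 1e-6
        # fitted means agree even if a little mass moves to the inflation part
        assert np.mean(np.abs(zinb.fitted_mean - nb.fitted_mean)) < 0.05

    def test_parameter_recovery_within_three_se(self, toy_design):
        rng = np.random.default_rng(16)
        n = 5000
        X = pd.concat([toy_design] * 3, ignore_index=True).iloc[:n]
        A = X.to_numpy()
        beta = np.array([0.4, 0.25, -0.4])
        gamma = np.array([-0.8, 0.4, 0.0])
        r = 2.0
        mu = np.exp(A @ beta)
        y = np.where(
            rng.random(n) < expit(A @ gamma),
            0,
            rng.negative_binomial(r, r / (r + mu)),
        )
        fit = fc.fit_zinb(X, y)
        assert fit.converged
        for name, true in zip(X.columns, beta):
            assert abs(fit.beta[name] - true) < 3 * max(fit.se_beta[name], 1e-3)

    def test_nesting_chain_on_overdispersed_fixture(self, toy_design):
        rng = np.random.default_rng(17)
        A = toy_design.to_numpy()
        r = 1.5
        mu = np.exp(A @ [0.4, 0.3, -0.4])
        y = np.where(
            rng.random(len(A)) < 0.25, 0, rng.negative_binomial(r, r / (r + mu))
        )
        pois = fc.fit_poisson(toy_design, y)
        nb = fc.fit_negbin(toy_design, y)
        zip_ = fc.fit_zip(toy_design, y)
        zinb = fc.fit_zinb(toy_design, y)
        assert pois.loglik <= zip_.loglik
        assert pois.loglik <= nb.loglik <= zinb.loglik + 1e-9
        assert zip_.loglik <= zinb.loglik + 1e-9


def central_gradient(f, x, h=1e-5):
    """Central finite differences (forward differences are too noisy for
    objectives of magnitude ~1e3 at tolerance 1e-6)."""
    g = np.zeros_like(x, dtype=float)
    for j in range(len(x)):
        e = np.zeros_like(g)
        e[j] = h
        g[j] = (f(x + e) - f(x - e)) / (2 * h)
    return g


class TestFirstOrderConditions:
    def test_score_vanishes_at_mle(self, toy_design, zip_counts):
        """Per-observation score below 1e-6 at the reported optimum."""
        y, _, _ = zip_counts
        n = len(y)
        pois = fc.fit_poisson(toy_design, y)
        grad = central_gradient(
            lambda b: fc.neg_log_likelihood("poisson", b, toy_design, y),
            pois.beta.to_numpy(),
        )
        assert np.max(np.abs(grad)) / n < 1e-6
        zipf = fc.fit_zip(toy_design, y)
        params = np.r_[zipf.beta.to_numpy(), zipf.gamma.to_numpy()]
        grad = central_gradient(
            lambda p: fc.neg_log_likelihood("zip", p[:3], toy_design, y, gamma=p[3:]),
            params,
        )
        assert np.max(np.abs(grad)) / n < 1e-6


class TestCompareModels:
    def test_aic_identity(self, toy_design, zip_counts):
        y, _, _ = zip_counts
        fit = fc.fit_poisson(toy_design, y)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)
        assert fit.k == 3

    def test_residual_mean_recomputed_directly(self, toy_design, zip_counts):
        y, _, _ = zip_counts
        fit = fc.fit_poisson(toy_design, y)
        _, mean, _ = fit.residual_summary
        assert mean == pytest.approx(np.mean(y - fit.fitted_mean), abs=1e-12)

    def test_zip_has_smaller_aic_on_zip_data(self, toy_design, zip_counts):
        y, _, _ = zip_counts
        table = fc.compare_models(
            [fc.fit_poisson(toy_design, y), fc.fit_zip(toy_design, y)]
        )
        assert table.loc["zip", "aic"] < table.loc["poisson", "aic"]

    def test_mismatched_data_rejected(self, toy_design, zip_counts):
        y, _, _ = zip_counts
        other = y.copy()
        other[0] += 1
        with pytest.raises(ValueError, match="fingerprint"):
            fc.compare_models(
                [fc.fit_poisson(toy_design, y), fc.fit_poisson(toy_design, other)]
            )


class TestSummaryTable:
    def test_summary_blocks_and_codes(self, toy_design, zip_counts):
        y, _, _ = zip_counts
        summ = fc.fit_zip(toy_design, y).summary()
        assert set(summ["part"]) == {"count", "inflation"}
        assert len(summ) == 6
        assert set(summ.columns) == {"part", "term", "estimate", "se", "z", "p", "code"}
        strong = summ[summ["p"] < 0.001]
        assert (strong["code"] == "***").all()
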