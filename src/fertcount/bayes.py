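"""Bayesian Poisson regression via adaptive random-walk Metropolis.

The Poisson log-mean model of :mod:`fertcount.models` is given
independent normal priors beta_j ~ N(0, tau) on every coefficient.
Following the convention of the BUGS/JAGS family of samplers, the prior
scale parameter is read as a *precision* (the default 1e-3 is a vague
prior with variance 1000); a variance reading is selectable via
``MCMCConfig.prior_is_variance``.

The posterior has no closed-form full conditionals, so sampling uses a
componentwise random-walk Metropolis kernel: per sweep each coefficient
receives a Gaussian proposal whose scale is initialised from the ML
standard errors and adapted toward a 44% acceptance rate during
burn-in, then frozen.  Chains start at the MLE plus a small
chain-specific jitter.  Diagnostics are the ones demographers report
from such runs: posterior means/SDs, lag-l autocorrelation, effective
sample size (initial-positive-sequence truncation), and DIC
(mean deviance D-bar, penalty pD = D-bar - D(posterior mean), and the
penalized deviance D-bar + pD).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .models import BirthCountModel


@dataclasses.dataclass
class MCMCConfig:
    """Sampler settings: 3 chains of 1000 iterations, 100 burn-in, by default."""

    n_chains: int = 3
    n_iter: int = 1000
    burn_in: int = 100
    thin: int = 1
    prior_mean: float = 0.0
    prior_precision: float = 1e-3
    prior_is_variance: bool = False  # read prior_precision as a variance instead
    seed: int = 0
    step_scale: np.ndarray | float | None = None  # None = auto from MLE SEs

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_precision <= 0:
            raise ValueError("prior precision must be positive")

    @property
    def prior_sd(self) -> float:
        if self.prior_is_variance:
            return float(np.sqrt(self.prior_precision))
        return float(1.0 / np.sqrt(self.prior_precision))


@dataclasses.dataclass
class PosteriorDraws:
    """Kept MCMC draws: (chains, iterations, parameters) array."""

    draws: np.ndarray
    acceptance_rate: np.ndarray  # per chain
    param_names: list

    def __post_init__(self):
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("draws contain non-finite values")

    @property
    def n_kept(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_frame(self) -> pd.DataFrame:
        """Long export: chain, iteration, then one column per parameter."""
        chains, iters, p = self.draws.shape
        idx = pd.MultiIndex.from_product(
            [range(chains), range(iters)], names=["chain", "iteration"]
        )
        return pd.DataFrame(self.flat(), index=idx, columns=self.param_names).reset_index()


def poisson_loglik(beta, X, y, offset=None) -> float:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    eta = (0.0 if offset is None else np.asarray(offset, dtype=float)) + X @ beta
    return float(np.sum(y * eta - np.exp(eta) - gammaln(y + 1)))


def log_posterior(beta, X, y, offset, config: MCMCConfig) -> float:
    """Poisson log-likelihood plus independent normal log-priors."""
    beta = np.asarray(beta, dtype=float)
    if np.asarray(X).shape[1] != beta.shape[0]:
        raise ValueError("beta length must match design-matrix width")
    sd = config.prior_sd
    lp = -0.5 * np.sum(((beta - config.prior_mean) / sd) ** 2)
    lp -= beta.size * (0.5 * np.log(2 * np.pi) + np.log(sd))
    return poisson_loglik(beta, X, y, offset) + lp


def sample_posterior(X, y, offset=None, config: MCMCConfig | None = None,
                     param_names=None) -> PosteriorDraws:
    """Run componentwise adaptive random-walk Metropolis chains.

    Deterministic given ``config.seed``.  Adaptation happens only during
    burn-in; burn-in and thinning are applied before returning.
    """
    config = config or MCMCConfig()
    if isinstance(X, pd.DataFrame):
        param_names = param_names or list(X.columns)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    param_names = param_names or [f"b{j}" for j in range(p)]
    offs = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    # ML fit supplies the chain starting point and proposal scales
    mle = BirthCountModel(y, X, offset=offs, family="poisson").fit()
    beta0 = mle.beta.to_numpy()
    se = np.where(mle.se_beta.to_numpy() > 0, mle.se_beta.to_numpy(), 0.01)
    if config.step_scale is None:
        base_scale = 2.4 * se
    else:
        base_scale = np.broadcast_to(
            np.asarray(config.step_scale, dtype=float), (p,)
        ).copy()

    sd = config.prior_sd
    prior_mean = config.prior_mean

    def logpost_terms(eta, beta):
        ll = np.sum(y * eta - np.exp(eta))
        lp = -0.5 * np.sum(((beta - prior_mean) / sd) ** 2)
        return ll + lp  # constants dropped (cancel in MH ratio)

    n_kept = (config.n_iter - config.burn_in) // config.thin
    draws = np.empty((config.n_chains, n_kept, p))
    acc_rates = np.empty(config.n_chains)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        scale = base_scale.copy()
        beta = beta0 + 0.1 * se * rng.standard_normal(p)
        eta = offs + X @ beta
        lp = logpost_terms(eta, beta)
        acc_block = np.zeros(p)
        block = 0
        accepted = proposals = 0
        kept = 0
        for it in range(config.n_iter):
            adapting = it < config.burn_in
            for j in range(p):
                delta = scale[j] * rng.standard_normal()
                beta_new = beta.copy()
                beta_new[j] += delta
                eta_new = eta + X[:, j] * delta
                lp_new = logpost_terms(eta_new, beta_new)
                if np.log(rng.random()) < lp_new - lp:
                    beta, eta, lp = beta_new, eta_new, lp_new
                    if adapting:
                        acc_block[j] += 1
                    else:
                        accepted += 1
                if not adapting:
                    proposals += 1
            if adapting:
                block += 1
                if block == 20:  # adapt toward 44% acceptance, Robbins-Monro style
                    scale *= np.exp(acc_block / block - 0.44)
                    acc_block[:] = 0
                    block = 0
            else:
                since = it - config.burn_in
                if since % config.thin == 0 and kept < n_kept:
                    draws[c, kept] = beta
                    kept += 1
        if proposals == 0:
            raise RuntimeError("no post-burn-in proposals; check config")
        acc_rates[c] = accepted / proposals
        if acc_rates[c] == 0:
            raise RuntimeError("zero acceptance after adaptation (step-scale failure)")
    return PosteriorDraws(draws=draws, acceptance_rate=acc_rates, param_names=param_names)


# ---------------------------------------------------------------------------
# diagnostics

def autocorrelation(chain, lag: int) -> float:
    """Sample autocorrelation at ``lag``: Pearson correlation between the
    chain and itself ``lag`` steps earlier.  NaN for constant chains."""
    x = np.asarray(chain, dtype=float)
    if lag < 0 or lag >= len(x):
        raise ValueError("lag must satisfy 0 <= lag < len(chain)")
    if np.ptp(x) == 0:
        return float("nan")
    if lag == 0:
        return 1.0
    a, b = x[:-lag], x[lag:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def effective_sample_size(chains) -> float:
    """ESS = N / (1 + 2 sum rho_l), initial-positive-sequence truncation.

    ``chains`` is a 1-D series or a (chains, iterations) array; the
    autocorrelation is averaged across chains at each lag and the sum
    truncated at the first lag pair with nonpositive total.
    """
    arr = np.atleast_2d(np.asarray(chains, dtype=float))
    n_chains, n_iter = arr.shape
    if n_iter < 10:
        raise ValueError("need at least 10 draws per chain")
    if all(np.ptp(row) == 0 for row in arr):
        raise ValueError("constant chains have undefined ESS")
    max_lag = n_iter - 2
    rho_sum = 0.0
    lag = 1
    while lag + 1 <= max_lag:
        rho_even = np.nanmean([autocorrelation(row, lag) for row in arr])
        rho_odd = np.nanmean([autocorrelation(row, lag + 1) for row in arr])
        if rho_even + rho_odd <= 0:
            break
        rho_sum += rho_even + rho_odd
        lag += 2
    n_total = n_chains * n_iter
    return float(min(n_total, n_total / (1.0 + 2.0 * rho_sum)))


def dic(draws: PosteriorDraws | np.ndarray, X, y, offset=None):
    """Deviance information criterion pieces.

    D(beta) = -2 loglik(beta); returns (mean deviance D-bar, penalty
    pD = D-bar - D(posterior mean), penalized deviance D-bar + pD).
    """
    flat = draws.flat() if isinstance(draws, PosteriorDraws) else np.atleast_2d(draws)
    if flat.size == 0:
        raise ValueError("no draws")
    devs = np.array([-2.0 * poisson_loglik(b, X, y, offset) for b in flat])
    mean_dev = float(devs.mean())
    d_at_mean = -2.0 * poisson_loglik(flat.mean(axis=0), X, y, offset)
    penalty = mean_dev - float(d_at_mean)
    return mean_dev, penalty, mean_dev + penalty


@dataclasses.dataclass
class MCMCDiagnostics:
    """Posterior summaries plus ESS/autocorrelation and DIC."""

    posterior_mean: pd.Series
    posterior_sd: pd.Series
    ess: pd.Series
    autocorr: pd.DataFrame  # lags x parameters
    mean_deviance: float
    penalty: float
    penalized_deviance: float

    def summary(self) -> pd.DataFrame:
        """Per-coefficient posterior mean, SD and effective size."""
        return pd.DataFrame(
            {"mean": self.posterior_mean, "sd": self.posterior_sd, "ess": self.ess}
        )


def diagnostics(draws: PosteriorDraws, X, y, offset=None, max_lag: int = 50) -> MCMCDiagnostics:
    flat = draws.flat()
    names = draws.param_names
    mean = pd.Series(flat.mean(axis=0), index=names)
    sd = pd.Series(flat.std(axis=0, ddof=1), index=names)
    ess = pd.Series(
        [effective_sample_size(draws.draws[:, :, j]) for j in range(flat.shape[1])],
        index=names,
    )
    lags = range(0, min(max_lag, draws.draws.shape[1] - 1) + 1)
    ac = pd.DataFrame(
        {
            name: [
                np.nanmean([autocorrelation(draws.draws[c, :, j], lag)
                            for c in range(draws.draws.shape[0])])
                for lag in lags
            ]
            for j, name in enumerate(names)
        },
        index=list(lags),
    )
    d_bar, pd_pen, d_pen = dic(draws, X, y, offset)
    return MCMCDiagnostics(
        posterior_mean=mean,
        posterior_sd=sd,
        ess=ess,
        autocorr=ac,
        mean_deviance=d_bar,
        penalty=pd_pen,
        penalized_deviance=d_pen,
    )


# ---------------------------------------------------------------------------
# model object (statsmodels-style wrapper)

@dataclasses.dataclass
class PosteriorResults:
    """Fit output: draws plus diagnostics, with a summary() table."""

    draws: PosteriorDraws
    diagnostics: MCMCDiagnostics
    config: MCMCConfig

    def summary(self) -> pd.DataFrame:
        return self.diagnostics.summary()


class BayesianPoissonModel:
    """Bayesian Poisson regression with independent normal priors."""

    def __init__(self, endog, exog, offset=None):
        self.exog = exog
        self.y = np.asarray(endog, dtype=float)
        self.offset = offset

    @classmethod
    def from_person_years(cls, table: pd.DataFrame, predictors=None):
        if predictors is None:
            predictors = [
                c for c in table.columns
                if c not in ("woman_id", "g", "exposure_years", "births")
            ]
        return cls(
            table["births"].to_numpy(),
            table[predictors],
            offset=np.log(table["exposure_years"].to_numpy(dtype=float)),
        )

    def fit(self, config: MCMCConfig | None = None) -> PosteriorResults:
        config = config or MCMCConfig()
        draws = sample_posterior(self.exog, self.y, self.offset, config)
        diag = diagnostics(draws, np.asarray(self.exog, dtype=float), self.y, self.offset)
        return PosteriorResults(draws=draws, diagnostics=diag, config=config)


# ---------------------------------------------------------------------------
# plots

def plot_trace(draws: PosteriorDraws, path=None, params=None):
    """Trace plots per parameter (one panel each), optionally saved."""
    return _panel_plot(draws, "trace", path, params)


def plot_density(draws: PosteriorDraws, path=None, params=None):
    """Posterior density (smoothed histogram) per parameter."""
    return _panel_plot(draws, "density", path, params)


def plot_autocorrelation(draws: PosteriorDraws, path=None, params=None, max_lag=40):
    """Autocorrelation stem plots per parameter."""
    return _panel_plot(draws, "acf", path, params, max_lag=max_lag)


def _panel_plot(draws, kind, path, params, max_lag=40):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = params or draws.param_names
    idx = [draws.param_names.index(n) for n in names]
    ncol = min(3, len(names))
    nrow = -(-len(names) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 2.5 * nrow), squeeze=False)
    for ax, name, j in zip(axes.ravel(), names, idx):
        if kind == "trace":
            for c in range(draws.draws.shape[0]):
                ax.plot(draws.draws[c, :, j], lw=0.5)
        elif kind == "density":
            ax.hist(draws.flat()[:, j], bins=40, density=True)
        else:
            acf = [
                np.nanmean([autocorrelation(draws.draws[c, :, j], lag)
                            for c in range(draws.draws.shape[0])])
                for lag in range(max_lag + 1)
            ]
            ax.vlines(range(max_lag + 1), 0, acf)
            ax.axhline(0, color="k", lw=0.5)
        ax.set_title(name, fontsize=8)
    for ax in axes.ravel()[len(names):]:
        ax.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
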