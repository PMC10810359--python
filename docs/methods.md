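# Methods

## Models

Let `y_i` be the number of births to woman (or person-year row) `i`
during the reference window, `x_i` her covariate row, and `E_i` her
years of exposure. All four working models use the log link with the
exposure offset, `log mu_i = log E_i + x_i' beta`:

* **Poisson**: `y_i ~ Pois(mu_i)`; equidispersed.
* **Negative binomial (NB2)**: success probability
  `P_i = r / (r + mu_i)` and dispersion `r > 0`, so
  `Var(y) = mu + mu^2 / r`; `r -> inf` recovers the Poisson.
* **Zero-inflated Poisson (ZIP)**: a logistic model for structural
  zeros, `theta_i = expit(x_i' gamma)` (no offset in the inflation
  part — eligibility does not scale with exposure), mixed with the
  Poisson count process:
  `P(y=0) = theta + (1-theta) e^{-mu}`, `E(y) = mu (1-theta)`,
  `Var(y) = mu (1-theta)(1 + theta mu)`. Note the variance follows
  from `E(y^2) = (1-theta)(mu + mu^2)`; a widely copied variant with
  `theta mu^2` in the bracket fails a Monte-Carlo check and is not
  used.
* **ZINB**: NB2 count part plus the same logistic inflation. (Sources
  that tabulate ZINB results often never write its likelihood; this is
  the standard construction.)

Both inflated models use the same predictor set in both parts.
Standard errors come from the observed information at the MLE,
p-values are two-sided normal, 95% intervals use z = 1.96 (matching
conventional reported arithmetic), and AIC = -2 loglik + 2k with k
counting every free parameter (both coefficient blocks plus `r` where
present).

## Exposure tabulation

Time is measured in whole CMC months. The reference window is the
half-open interval `(interview - w, interview]` — the interview month
counts, the month `w` before it does not. A woman's age during month
`t` is `t - dob - 1` months: her birthday month still belongs to the
pre-birthday age group, so a woman aged exactly 240 months at interview
spends a whole 36-month window (ages 17–20) in group 15–19. Months and
births at ages outside [15, 50) are excluded (women outside the range
for the whole window contribute zero rows, not errors). With 5-year
groups and windows up to 60 months a woman touches at most two adjacent
groups; within the range, her exposure sums exactly to the window
length. The closed-form interval intersection is validated against a
month-by-month loop in the tests.

Because exposure below 15 and above 50 is truncated while the window is
anchored at the interview, group-level exposure at the extreme ages can
undercount the time at risk that produced the observed births; this is
a known limitation of person-year tabulation from a single interview
date, visible as upward-biased ASFRs in the extreme groups.

## Model-based predictive estimation and its bootstrap

For a finite population of `N` women with person-year rows already
tabulated, a replicate draws a simple random sample of `n` *women*
without replacement (a woman's rows travel with her), fits one of the
working models to the sampled rows, and forms

```
B_hat_g = sum of observed births (sampled rows in g)
        + sum of predicted E[y|x] (non-sampled rows in g)
```

with `E[y|x] = mu` (Poisson/NB) or `mu (1-theta)` (ZIP/ZINB) — always
nonnegative, unlike linear-model predictions. Exposure needs no model
and is taken from all women. ASFR/TFR/GFR/GRR then come from the
ordinary formulas; with the whole population sampled the estimator
reduces exactly to the direct estimates. Over `B` replicates the
package reports, per family and measure, the mean estimate,
`bias = mean - direct full-data value` and
`RMSE = sqrt(mean (estimate - direct)^2)`; replicates whose fit fails
to converge are dropped and counted. The reporting table prints
"estimate (RMSE)" per family with the row-minimum RMSE starred.

Two properties of this design matter for interpretation:

* Against the *realized* full-data reference, the estimator is pulled
  toward the model mean and away from the realized group totals, so
  within one population its bootstrap mean does not converge to the
  direct value — unbiasedness under a correctly specified model is a
  statement over regenerated populations, and that is how the test
  suite checks it.
* Replicate fits default to a parsimonious demographic core
  (`CORE_PREDICTORS`: intercept, age, residence, education, wealth
  dummy, children ever born, daughters, first-birth interval). Fitting
  all 24 survey covariates — 50 parameters for the inflated families —
  on samples of a few hundred women leaves rarely-used contraceptive
  and occupation dummies unidentified and replicate fits unstable.

## Bayesian Poisson regression

Independent priors `beta_j ~ N(0, tau)` on every coefficient; the scale
parameter is read as a *precision* following the convention of
Gibbs-sampling engines, so the default 1e-3 is a vague prior with
variance 1000 (a literal variance of 1e-3 would contradict the
observation that posterior means track the MLEs; both readings are
selectable). The sampler is componentwise random-walk Metropolis:
chains start at the Poisson MLE plus a small jitter, proposal scales
start at 2.4 × the ML standard errors and adapt toward 44% acceptance
in blocks of 20 sweeps during burn-in only, then freeze (so the kept
chain is a valid Markov chain). Defaults — 3 chains, 1000 iterations,
burn-in 100, thin 1 — mirror common practice for this model size; the
linear predictor is updated incrementally per coordinate, so a sweep
costs O(np).

Diagnostics: lag-l autocorrelation is the Pearson correlation between
the chain and itself l steps earlier; the effective sample size is
`N / (1 + 2 sum_l rho_l)` with the sum truncated at the first
consecutive lag pair whose total is nonpositive (initial-positive-
sequence rule), capped at N and averaged across chains;
`DIC = D_bar + pD` with `D(beta) = -2 loglik`, `D_bar` the posterior
mean deviance and `pD = D_bar - D(posterior mean)` (the standard
penalty, consistent with additive deviance reporting).

## Synthetic populations

The generator inverts the response models: it draws raw DHS-coded
covariates, builds the same 25-column design matrix the modelling stage
uses, draws the window birth count from the configured family with
mean `exp(x' beta)`, scatters the births over distinct window months
(≥ 9 months apart when feasible — a biological plausibility floor,
relaxed rather than failing — marginally uniform over the window),
and finally masks husband's age (blank) and the pregnancy-termination
indicator (code 9) at the configured rates.

Defaults are chosen to emulate a South-Asian ever-married DHS sample:

* `count_coefs` / `inflation_coefs`: the published 3-year-window
  Poisson and zero-inflation estimates, so effect sizes and the ~0.3
  marginal zero-inflation are survey-realistic;
* `dispersion_r = 2` (overdispersion of the NB/ZINB families; not
  identified from published tables);
* ages weighted by 5-year group (6/15/20/20/16/13/10%) — ever-married
  teenagers are rare — with uniform months within group; a uniform age
  distribution is available via `covariate_spec`;
* missingness: husband's age 5%; pregnancy termination 64.37%, the
  fraction implied by the survey's observed/total counts;
* remaining covariates: independent categorical draws with realistic
  base-category shares, bounded uniforms for wealth score,
  first-birth interval and husband's age.

What the generator does **not** emulate: the joint covariate
distribution (everything but the daughter count is drawn
independently, so e.g. children-ever-born is uncorrelated with age —
this inflates young-age ASFRs and hence TFR relative to real data),
survey clustering/stratification and weights, and within-woman birth
spacing beyond the 9-month floor. Passing tests therefore demonstrate
correctness of the estimators under a known data-generating process,
not agreement with any real survey's published rates.

## Numerical choices

* Poisson: Newton iterations, tolerance 1e-10. NB: BFGS on
  (beta, dispersion) warm-started from the Poisson fit; a fitted
  `alpha = 1/r` below 1e-4 is treated as the equidispersion boundary —
  `r` is capped at 1e6, the Poisson coefficients are reported and the
  `r_cap` flag set.
* ZIP/ZINB: BFGS (gradient tolerance 5e-8) warm-started from the
  Poisson fit plus a moment start for the inflation intercept (excess
  zero fraction); stalls are polished by a Nelder-Mead pass and a BFGS
  restart. ZINB additionally warm-starts from the nested ZIP fit and
  falls back to it at the dispersion cap if the optimizer cannot beat
  it. Data with no zeros pin `theta` at 1e-8 with a `theta_zero` flag.
* Where the statsmodels Hessian inversion yields non-finite standard
  errors (weakly identified inflation parameters), observed-information
  SEs are recomputed from the package's own likelihood; directions with
  non-positive information are reported as NaN, never zero.
* Comparison-table residuals are response residuals `y - E[y|x]`.
* `round half away from zero` for the imputation split, with the
  complement taken so the parts always reconcile to the total.
* ASFR for a group with neither exposure nor births is 0 and the group
  is flagged; births without exposure are an error.

## Problem sizes

The test suite and acceptance script run populations of 400–1200 women
(1500–1900 person-year rows), bootstraps of 200 replicates, ML
recovery at n = 2000–5000, MCMC at the default 3 × 1000 iterations,
and ESS checks on a 100,000-draw AR(1) chain — sizes at which every
statistical check has comfortable Monte-Carlo margin while the whole
suite runs in about a minute.

## Known limitations

* Exposure truncation at ages 15/50 (above) biases extreme-age ASFRs.
* The ZIP/ZINB inflation part can be weakly identified on small
  samples or low-inflation data; flags and NaN SEs make this visible
  rather than hiding it.
* Bayesian fitting covers the Poisson model only; the classical
  families are fit by ML.
* Rates are per *ever-married* woman; no all-women adjustment factor is
  applied, and GRR assumes no mortality across the reproductive span.
* Design-based corrections (survey weights, clustering) are out of
  scope; sampling in the bootstrap is SRSWOR of women.
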