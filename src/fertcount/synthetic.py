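"""Synthetic DHS-style populations with known ground truth.

The generator inverts the package's response models: covariates are
drawn per a configurable specification (categorical draws for the dummy
sources, bounded uniforms for the continuous ones), the 25-column
design matrix is built with exactly the same recoding rules the
modelling stage uses, and the birth count for the configured reference
window is drawn from the chosen family with mean mu_i = exp(x_i' beta)
(zero-inflation probability theta_i = expit(x_i' gamma) for ZIP/ZINB,
dispersion r for NB/ZINB).  Birth dates are then scattered over the
window months and realistic missingness is punched into husband age and
the pregnancy-termination indicator.

Default coefficients are the published 3-year-window Poisson estimates
(count part) and the matching zero-inflation estimates, so the default
population reproduces the magnitudes of a Pakistani ever-married DHS
sample; the joint covariate distribution is deliberately simple
(independent draws), which is all the downstream tests require.

Everything is reproducible bit-for-bit from ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import pandas as pd

from . import recode
from .recode import DESIGN_COLUMNS, WomanRecord

#: Count-part defaults: published Poisson coefficients for 3-year birth
#: counts (log-mean scale, Table-coded covariates).
DEFAULT_COUNT_COEFS = {
    "Intercept": 2.398,
    "Res_age": -0.094,
    "Residence": -0.0877,
    "Age_husbnd": -0.0142,
    "Sindh": -0.0039,
    "KPK": -0.0879,
    "Balochistan": -0.101,
    "ICT": 0.0519,
    "FATA": -0.0649,
    "Edu": 0.0731,
    "WI": -0.1249,
    "Num_mem": 0.0211,
    "Num_daughter": 0.207,
    "MTFBI": 0.0046,
    "Cont_Pill": -0.0417,
    "IUD": -0.2801,
    "Cont_Inj": 0.0624,
    "Cont_female": -0.5299,
    "Cont_male": 0.037,
    "Cont_withdrawal": -0.1376,
    "Cont_other": 0.0465,
    "Preg_term_new": -0.0485,
    "Prof_tech": 0.0923,
    "Prof_Agr": 0.0596,
    "Prof_other": -0.129,
}

#: Inflation-part defaults (logit scale), from the matching ZIP fit.
DEFAULT_INFLATION_COEFS = {
    "Intercept": -17.226,
    "Res_age": 0.4514,
    "Residence": 0.658,
    "Age_husbnd": 0.0652,
    "Sindh": -0.3242,
    "KPK": 0.336,
    "Balochistan": -1.7996,
    "ICT": -0.3946,
    "FATA": 0.2322,
    "Edu": -0.1968,
    "WI": 1.5051,
    "Num_mem": -0.7039,
    "Num_daughter": -0.1655,
    "MTFBI": -0.0166,
    "Cont_Pill": 1.0315,
    "IUD": -0.263,
    "Cont_Inj": -1.7268,
    "Cont_female": 0.8415,
    "Cont_male": 0.3884,
    "Cont_withdrawal": 0.0787,
    "Cont_other": 1.1738,
    "Preg_term_new": 0.4537,
    "Prof_tech": -1.5429,
    "Prof_Agr": 1.0635,
    "Prof_other": 0.6009,
}

DEFAULT_COVARIATE_SPEC = {
    "interview_cmc": 1415,  # November 2017
    "interview_jitter_months": 6,
    "age_range_months": (181, 599),  # age at interview within [15, 50) years
    # age-group weights 15-19 ... 45-49 emulating an ever-married sample
    # (few ever-married teenagers); None = uniform over age_range_months
    "age_group_weights": (0.06, 0.15, 0.20, 0.20, 0.16, 0.13, 0.10),
    "region_probs": {1: 0.40, 2: 0.20, 3: 0.15, 4: 0.10, 6: 0.05, 8: 0.10},
    "urban_prob": 0.4,
    "edu_probs": (0.45, 0.20, 0.25, 0.10),
    "wealth_range": (-2.0, 2.0),
    "num_mem_range": (0, 8),
    "mtfbi_range": (0, 120),
    "mtfbi_negative_prob": 0.03,
    "contraceptive_probs": {0: 0.66, 1: 0.05, 2: 0.03, 3: 0.06, 4: 0.08, 5: 0.05, 6: 0.04, 7: 0.03},
    "occupation_probs": {0: 0.60, 1: 0.12, 2: 0.13, 3: 0.15},
    "husband_age_range": (18, 70),
    "preg_term_prob": 0.25,
}

#: Missingness: the pregnancy-termination rate is the fraction implied
#: by the survey's observed/total counts ((50495-17993)/50495); the
#: husband-age rate is a modest conventional choice.
DEFAULT_MISSING_RATES = {"husband_age": 0.05, "preg_term": 0.6437}

MIN_BIRTH_GAP_MONTHS = 9  # biological plausibility floor, relaxed if infeasible


def _coef_vector(coefs, default) -> np.ndarray:
    """Canonicalize a name->value mapping (or full vector) to design order."""
    if coefs is None:
        coefs = default
    if isinstance(coefs, dict):
        unknown = set(coefs) - set(DESIGN_COLUMNS)
        if unknown:
            raise ValueError(f"unknown coefficient name(s): {sorted(unknown)}")
        return np.array([float(coefs.get(c, 0.0)) for c in DESIGN_COLUMNS])
    v = np.asarray(coefs, dtype=float)
    if v.shape != (len(DESIGN_COLUMNS),):
        raise ValueError(
            f"coefficient vector must have length {len(DESIGN_COLUMNS)}"
        )
    return v


@dataclasses.dataclass
class SyntheticConfig:
    """Ground-truth parameters and sampling spec for a synthetic population."""

    n_women: int = 1000
    family: str = "poisson"
    window_months: int = 36
    count_coefs: dict | np.ndarray | None = None
    inflation_coefs: dict | np.ndarray | None = None
    dispersion_r: float = 2.0
    covariate_spec: dict | None = None
    missing_rates: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_women < 0:
            raise ValueError("n_women must be nonnegative")
        if self.family not in ("poisson", "negbin", "zip", "zinb"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.window_months not in (12, 36, 60):
            raise ValueError("window_months must be one of 12, 36, 60")
        if self.dispersion_r <= 0:
            raise ValueError("dispersion_r must be positive")
        self.beta = _coef_vector(self.count_coefs, DEFAULT_COUNT_COEFS)
        self.gamma = _coef_vector(self.inflation_coefs, DEFAULT_INFLATION_COEFS)
        spec = dict(DEFAULT_COVARIATE_SPEC)
        spec.update(self.covariate_spec or {})
        self.covariate_spec = spec
        rates = dict(DEFAULT_MISSING_RATES)
        rates.update(self.missing_rates or {})
        if any(not 0 <= v <= 1 for v in rates.values()):
            raise ValueError("missing rates must lie in [0, 1]")
        self.missing_rates = rates


@dataclasses.dataclass
class SyntheticPopulation:
    """Generated population: woman frame, long births file, ground truth."""

    women: pd.DataFrame
    births: pd.DataFrame
    design: pd.DataFrame  # 25-column design matrix (pre-missingness truth)
    truth: dict


def _draw_categorical(rng, probs: dict, n: int) -> np.ndarray:
    codes = np.array(sorted(probs))
    p = np.array([probs[c] for c in codes], dtype=float)
    p = p / p.sum()
    return rng.choice(codes, size=n, p=p)


def _draw_covariates(rng, spec: dict, n: int) -> pd.DataFrame:
    lo, hi = spec["age_range_months"]
    weights = spec.get("age_group_weights")
    if weights is None:
        age_months = rng.integers(lo, hi + 1, size=n)
    else:
        w = np.asarray(weights, dtype=float)
        group = rng.choice(7, size=n, p=w / w.sum())
        g_lo = np.maximum(lo, (15 + 5 * group) * 12 + 1)
        g_hi = np.minimum(hi, (20 + 5 * group) * 12 - 1)
        age_months = rng.integers(g_lo, g_hi + 1)
    ivw = spec["interview_cmc"] + rng.integers(
        -spec["interview_jitter_months"], spec["interview_jitter_months"] + 1, size=n
    )
    num_mem = rng.integers(spec["num_mem_range"][0], spec["num_mem_range"][1] + 1, size=n)
    num_dau = rng.integers(0, num_mem + 1)
    mtfbi = rng.integers(spec["mtfbi_range"][0], spec["mtfbi_range"][1] + 1, size=n)
    mtfbi = np.where(
        rng.random(n) < spec["mtfbi_negative_prob"], recode.MTFBI_NEGATIVE_CODE, mtfbi
    )
    return pd.DataFrame(
        {
            "woman_id": np.arange(n),
            "dob_cmc": ivw - age_months,
            "interview_cmc": ivw,
            "v024": _draw_categorical(rng, spec["region_probs"], n),
            "v025": np.where(rng.random(n) < spec["urban_prob"], 1, 2),
            "v106": rng.choice(4, size=n, p=np.asarray(spec["edu_probs"])),
            "v191": np.round(rng.uniform(*spec["wealth_range"], size=n), 5),
            "v201": num_mem,
            "v203": num_dau,
            "v221": mtfbi,
            "v239": (rng.random(n) < spec["preg_term_prob"]).astype(int),
            "v312": _draw_categorical(rng, spec["contraceptive_probs"], n),
            "v717": _draw_categorical(rng, spec["occupation_probs"], n),
            "v730": rng.integers(
                spec["husband_age_range"][0], spec["husband_age_range"][1] + 1, size=n
            ).astype(float),
        }
    )


def _draw_counts(rng, config: SyntheticConfig, X: np.ndarray) -> np.ndarray:
    mu = np.exp(X @ config.beta)
    if config.family == "poisson":
        return rng.poisson(mu)
    if config.family == "negbin":
        r = config.dispersion_r
        return rng.negative_binomial(r, r / (r + mu))
    from scipy.special import expit

    theta = expit(X @ config.gamma)
    structural_zero = rng.random(len(mu)) < theta
    if config.family == "zip":
        counts = rng.poisson(mu)
    else:  # zinb
        r = config.dispersion_r
        counts = rng.negative_binomial(r, r / (r + mu))
    return np.where(structural_zero, 0, counts)


def _scatter_months(rng, n_births: int, interview_cmc: int, window_months: int,
                    min_gap: int = MIN_BIRTH_GAP_MONTHS) -> list[int]:
    """Draw ``n_births`` distinct window months, >= min_gap apart if feasible."""
    if n_births == 0:
        return []
    if n_births > window_months:
        raise ValueError(
            f"cannot place {n_births} births in a {window_months}-month window"
        )
    months = np.arange(interview_cmc - window_months + 1, interview_cmc + 1)
    feasible = (n_births - 1) * min_gap < window_months
    draw = rng.choice(months, size=n_births, replace=False)
    if feasible:
        for _ in range(100):
            cand = np.sort(draw)
            if n_births == 1 or np.diff(cand).min() >= min_gap:
                return cand.tolist()
            draw = rng.choice(months, size=n_births, replace=False)
    return np.sort(draw).tolist()


def scatter_birth_dates(record: WomanRecord, window_months: int, seed: int) -> WomanRecord:
    """Return a copy of ``record`` with its births dated inside the window."""
    rng = np.random.default_rng(seed)
    cmcs = _scatter_months(rng, record.birth_count, record.interview_cmc, window_months)
    return dataclasses.replace(record, birth_cmcs=[int(c) for c in cmcs])


def inject_missingness(women: pd.DataFrame, missing_rates: dict, seed) -> pd.DataFrame:
    """Mask husband age (NaN) and pregnancy termination (code 9) at the given
    rates, independently across women."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = women.copy()
    n = len(out)
    rate = missing_rates.get("husband_age", 0.0)
    out.loc[rng.random(n) < rate, "v730"] = np.nan
    rate = missing_rates.get("preg_term", 0.0)
    out.loc[rng.random(n) < rate, "v239"] = 9
    return out


def generate_population(config: SyntheticConfig) -> SyntheticPopulation:
    """Generate a full synthetic population per the config (seed-deterministic)."""
    rng = np.random.default_rng(config.seed)
    women = _draw_covariates(rng, config.covariate_spec, config.n_women)
    if config.n_women == 0:
        births = pd.DataFrame(columns=["woman_id", "birth_cmc"])
        design = pd.DataFrame(columns=DESIGN_COLUMNS)
        for col in ("v209", "v238", "v208"):
            women[col] = pd.Series(dtype=int)
    else:
        design = recode.build_design_matrix(women)
        counts = _draw_counts(rng, config, design.to_numpy())
        rows = []
        for wid, ivw, k in zip(women["woman_id"], women["interview_cmc"], counts):
            for c in _scatter_months(rng, int(k), int(ivw), config.window_months):
                rows.append((wid, int(c)))
        births = pd.DataFrame(rows, columns=["woman_id", "birth_cmc"])
        for col, w in (("v209", 12), ("v238", 36), ("v208", 60)):
            women[col] = _window_counts(women, births, w)
        women = inject_missingness(women, config.missing_rates, rng)
    truth = {
        "family": config.family,
        "window_months": config.window_months,
        "n_women": config.n_women,
        "seed": config.seed,
        "count_coefs": dict(zip(DESIGN_COLUMNS, config.beta.tolist())),
        "inflation_coefs": dict(zip(DESIGN_COLUMNS, config.gamma.tolist())),
        "dispersion_r": config.dispersion_r,
        "missing_rates": config.missing_rates,
    }
    return SyntheticPopulation(women=women, births=births, design=design, truth=truth)


def _window_counts(women: pd.DataFrame, births: pd.DataFrame, window_months: int):
    """Count each woman's dated births inside (interview - w, interview]."""
    if births.empty:
        return np.zeros(len(women), dtype=int)
    merged = births.merge(
        women[["woman_id", "interview_cmc"]], on="woman_id", how="left"
    )
    in_w = (merged["birth_cmc"] > merged["interview_cmc"] - window_months) & (
        merged["birth_cmc"] <= merged["interview_cmc"]
    )
    per_woman = merged[in_w].groupby("woman_id").size()
    return (
        women["woman_id"].map(per_woman).fillna(0).astype(int).to_numpy()
    )


def write_population(pop: SyntheticPopulation, outdir) -> dict:
    """Write women.csv, births.csv and truth.json; returns the paths."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "women": outdir / "women.csv",
        "births": outdir / "births.csv",
        "truth": outdir / "truth.json",
    }
    pop.women.to_csv(paths["women"], index=False)
    pop.births.to_csv(paths["births"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(pop.truth, fh, indent=2)
    return paths
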