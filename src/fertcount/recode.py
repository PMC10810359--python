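"""Reading DHS-style women's recode files and building the design matrix.

The woman-level input is a rectangular CSV using DHS women's-recode
variable names (v024 region, v025 residence, v106 education, v191 wealth
score, v201/v203 child counts, v221 marriage-to-first-birth interval,
v312 contraceptive method, v717 occupation, v730 husband age, v239
pregnancy-termination indicator, v209/v238/v208 birth counts for the
1/3/5-year windows) plus ``dob_cmc`` and ``interview_cmc``.

Two imputation rules are applied before modelling:

* missing husband ages are replaced by the median of the observed ages
  (even counts: mean of the middle pair);
* missing pregnancy-termination indicators (code 9) are split 0/1 in the
  ratio of the observed zeros to observed ones, the first block of
  missing records (in file order) receiving 0.

``build_design_matrix`` then produces the fixed 25-column predictor
matrix (intercept + 24 predictors) used by every count model: five
region dummies with Punjab as base, urban-residence dummy, a positive
wealth-index dummy (v191 > 0), seven contraceptive-method dummies with
"not using" as base, three occupation dummies with "not working" as
base, and the continuous/ordinal covariates.  The marriage-to-first-birth
interval is set to 0 for the DHS "negative interval" code 996.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import yaml

#: Fixed design-matrix column order (intercept + 24 predictors).
DESIGN_COLUMNS = [
    "Intercept",
    "Res_age",
    "Residence",
    "Age_husbnd",
    "Sindh",
    "KPK",
    "Balochistan",
    "ICT",
    "FATA",
    "Edu",
    "WI",
    "Num_mem",
    "Num_daughter",
    "MTFBI",
    "Cont_Pill",
    "IUD",
    "Cont_Inj",
    "Cont_female",
    "Cont_male",
    "Cont_withdrawal",
    "Cont_other",
    "Preg_term_new",
    "Prof_tech",
    "Prof_Agr",
    "Prof_other",
]

#: Region codes carried by v024.  Only the six regions that enter the
#: dummy coding (Punjab base + five dummies) are legal model input.
REGION_DUMMIES = {2: "Sindh", 3: "KPK", 4: "Balochistan", 6: "ICT", 8: "FATA"}
REGION_BASE = 1  # Punjab

#: Contraceptive-method codes for v312 (package schema, documented in
#: the README): 0 none (base), then one code per dummy column.
CONTRACEPTIVE_DUMMIES = {
    1: "Cont_Pill",
    2: "IUD",
    3: "Cont_Inj",
    4: "Cont_female",
    5: "Cont_male",
    6: "Cont_withdrawal",
    7: "Cont_other",
}

#: Occupation codes for v717: 0 not working (base).
OCCUPATION_DUMMIES = {1: "Prof_tech", 2: "Prof_Agr", 3: "Prof_other"}

#: v221 code for a negative marriage-to-first-birth interval.
MTFBI_NEGATIVE_CODE = 996

REQUIRED_COLUMNS = [
    "woman_id",
    "dob_cmc",
    "interview_cmc",
    "v024",
    "v025",
    "v106",
    "v191",
    "v201",
    "v203",
    "v221",
    "v239",
    "v312",
    "v717",
    "v730",
]


@dataclasses.dataclass
class WomanRecord:
    """One survey respondent: CMC dates, raw covariates and birth history."""

    woman_id: int
    dob_cmc: int
    interview_cmc: int
    covariates: dict
    birth_count: int = 0
    birth_cmcs: list = dataclasses.field(default_factory=list)


def load_schema(path) -> dict:
    """Load a YAML column-name schema mapping external -> canonical names."""
    with open(path) as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise ValueError("schema file must contain a mapping of column names")
    return schema


def read_recode_csv(path, schema: dict | None = None) -> pd.DataFrame:
    """Read a woman-level recode CSV into a typed frame.

    ``schema`` optionally maps external column names to the canonical
    DHS names above.  Blank husband ages become NaN (missing); rows with
    non-integer CMC dates are reported with their (1-based) row numbers.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    bad_rows = []
    for col in ("dob_cmc", "interview_cmc"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        bad_rows.extend((int(i) + 1, col) for i in df.index[bad])
        if not bad.any():
            df[col] = vals.astype(int)
    if bad_rows:
        raise ValueError(f"non-integer CMC values at rows {bad_rows}")
    return df


def records_from_frame(df: pd.DataFrame, births: pd.DataFrame | None = None) -> list[WomanRecord]:
    """View a recode frame (plus optional long birth file) as WomanRecord objects."""
    birth_map: dict = {}
    if births is not None:
        birth_map = {
            wid: sorted(int(b) for b in grp["birth_cmc"])
            for wid, grp in births.groupby("woman_id")
        }
    records = []
    aux = [c for c in df.columns if c not in ("woman_id", "dob_cmc", "interview_cmc")]
    for row in df.itertuples(index=False):
        d = row._asdict()
        cmcs = birth_map.get(d["woman_id"], [])
        records.append(
            WomanRecord(
                woman_id=d["woman_id"],
                dob_cmc=int(d["dob_cmc"]),
                interview_cmc=int(d["interview_cmc"]),
                covariates={k: d[k] for k in aux},
                birth_count=len(cmcs),
                birth_cmcs=cmcs,
            )
        )
    return records


def impute_husband_age(df: pd.DataFrame) -> pd.DataFrame:
    """Replace missing v730 (husband age) by the median observed age.

    The even-count median is the mean of the middle pair.  Observed
    values are untouched.  Raises if every value is missing.
    """
    out = df.copy()
    observed = out["v730"].dropna()
    if observed.empty:
        raise ValueError("cannot impute husband age: all values missing")
    out["v730"] = out["v730"].fillna(float(observed.median()))
    return out


def split_preg_term_missing(
    n_observed_zero: int, n_observed_one: int, n_total: int
) -> tuple[int, int]:
    """Split ``n_total`` records 0/1 in the ratio of the observed indicator.

    Returns (n_assign_zero, n_assign_one) with
    ``n_assign_zero = round(n_observed_zero * n_total / (n_observed_zero
    + n_observed_one))`` (half away from zero) and the complement for the
    ones, so the two parts always reconcile to ``n_total``.
    """
    if min(n_observed_zero, n_observed_one, n_total) < 0:
        raise ValueError("counts must be nonnegative")
    denom = n_observed_zero + n_observed_one
    if denom == 0:
        raise ValueError("no observed pregnancy-termination values to split on")
    exact = n_observed_zero * n_total / denom
    n_zero = int(math.floor(exact + 0.5))  # round half away from zero (counts >= 0)
    return n_zero, n_total - n_zero


def impute_preg_term(df: pd.DataFrame, missing_code: int = 9) -> pd.DataFrame:
    """Fill missing v239 values by the observed-ratio split, in record order.

    The first block of missing records receives 0, the remainder 1,
    mirroring the proportional-allocation rule used for the survey data.
    """
    out = df.copy()
    is_missing = out["v239"] == missing_code
    if not is_missing.any():
        return out
    n0 = int((out["v239"] == 0).sum())
    n1 = int((out["v239"] == 1).sum())
    n_zero, _ = split_preg_term_missing(n0, n1, int(is_missing.sum()))
    idx = out.index[is_missing]
    out.loc[idx[:n_zero], "v239"] = 0
    out.loc[idx[n_zero:], "v239"] = 1
    return out


def _check_codes(series: pd.Series, legal, name: str) -> None:
    bad = ~series.isin(list(legal))
    if bad.any():
        raise ValueError(
            f"unknown {name} code(s) {sorted(series[bad].unique().tolist())}"
        )


def build_design_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Build the fixed 25-column design matrix from an imputed recode frame.

    Raises on unknown category codes (silent base-category assignment
    would corrupt the dummies) and on residual missing values.
    """
    needed = [c for c in REQUIRED_COLUMNS if c != "woman_id"]
    if df[needed].isna().any().any():
        raise ValueError("design matrix requires imputed data (NaNs present)")
    _check_codes(df["v024"], [REGION_BASE, *REGION_DUMMIES], "region (v024)")
    _check_codes(df["v025"], [1, 2], "residence (v025)")
    _check_codes(df["v106"], [0, 1, 2, 3], "education (v106)")
    _check_codes(df["v312"], [0, *CONTRACEPTIVE_DUMMIES], "contraceptive (v312)")
    _check_codes(df["v717"], [0, *OCCUPATION_DUMMIES], "occupation (v717)")
    _check_codes(df["v239"], [0, 1], "pregnancy termination (v239)")

    n = len(df)
    X = pd.DataFrame(index=df.index, columns=DESIGN_COLUMNS, dtype=float)
    X["Intercept"] = 1.0
    X["Res_age"] = (df["interview_cmc"] - df["dob_cmc"]) / 12.0
    X["Residence"] = (df["v025"] == 1).astype(float)  # 1 = urban
    X["Age_husbnd"] = df["v730"].astype(float)
    for code, col in REGION_DUMMIES.items():
        X[col] = (df["v024"] == code).astype(float)
    X["Edu"] = df["v106"].astype(float)
    X["WI"] = (df["v191"] > 0).astype(float)
    X["Num_mem"] = df["v201"].astype(float)
    X["Num_daughter"] = df["v203"].astype(float)
    mtfbi = df["v221"].astype(float)
    X["MTFBI"] = np.where((mtfbi == MTFBI_NEGATIVE_CODE) | (mtfbi < 0), 0.0, mtfbi)
    for code, col in CONTRACEPTIVE_DUMMIES.items():
        X[col] = (df["v312"] == code).astype(float)
    X["Preg_term_new"] = df["v239"].astype(float)
    for code, col in OCCUPATION_DUMMIES.items():
        X[col] = (df["v717"] == code).astype(float)
    assert X.shape == (n, len(DESIGN_COLUMNS))
    return X
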