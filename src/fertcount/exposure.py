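"""Person-year exposure tabulation (Lexis allocation at month resolution).

Individual birth-history records are converted into long-format
person-year data: each woman's months inside the reference window are
allocated to 5-year age groups 15-19 ... 45-49 (g = 0..6), and her
births are tabulated by the age group active at the birth month.  These
rows carry the births B_g (numerator) and woman-years of exposure E_g
(denominator / model offset) of the age-specific fertility rates.

Conventions (month is the atomic unit):

* the reference window is the half-open CMC interval
  ``(interview - window_months, interview]`` - the interview month
  counts, the month ``window_months`` before it does not;
* the woman's age during CMC month ``t`` is ``t - dob_cmc - 1`` months,
  i.e. her birthday month still belongs to the pre-birthday age group
  (a woman aged exactly 240 months at interview spent the whole of a
  36-month window, ages 17-20, in group 15-19);
* months (and births) at ages outside [15, 50) years are excluded, so a
  window of up to 60 months touches at most two adjacent groups and a
  woman fully inside reproductive ages contributes exactly the window
  length.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

N_AGE_GROUPS = 7
AGE_GROUP_LABELS = ["15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49"]
_AGE_MIN = 15 * 12  # age in months at entry to group 0
_AGE_MAX = 50 * 12  # first age month past group 6
_WIDTH = 5 * 12


@dataclasses.dataclass
class ExposureTable:
    """Aggregated births B_g and woman-years of exposure E_g by age group."""

    B: np.ndarray  # length-7 birth counts
    E: np.ndarray  # length-7 woman-years

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.B.shape != (N_AGE_GROUPS,) or self.E.shape != (N_AGE_GROUPS,):
            raise ValueError("B and E must be length-7 vectors")
        if (self.B < 0).any() or (self.E < 0).any():
            raise ValueError("births and exposure must be nonnegative")


def _age_months(cmc: np.ndarray | int, dob_cmc: np.ndarray | int):
    """Age in months during CMC month ``cmc`` for a woman born in ``dob_cmc``."""
    return np.asarray(cmc) - np.asarray(dob_cmc) - 1


def woman_exposure(dob_cmc: int, interview_cmc: int, window_months: int):
    """Split a woman's window months across 5-year age groups.

    Returns a list of ``(g, exposure_months)`` pairs (ascending g, only
    positive entries).  Months at ages outside [15, 50) are excluded.
    """
    if window_months <= 0:
        raise ValueError("window_months must be positive")
    if interview_cmc <= dob_cmc:
        raise ValueError("interview_cmc must exceed dob_cmc")
    # age (months) during the first and last window month
    age_lo = _age_months(interview_cmc - window_months + 1, dob_cmc)
    age_hi = _age_months(interview_cmc, dob_cmc)
    out = []
    for g in range(N_AGE_GROUPS):
        g_lo = _AGE_MIN + _WIDTH * g
        g_hi = g_lo + _WIDTH - 1
        months = min(age_hi, g_hi) - max(age_lo, g_lo) + 1
        if months > 0:
            out.append((g, int(months)))
    return out


def allocate_births(birth_cmcs, dob_cmc: int, interview_cmc: int, window_months: int):
    """Tabulate a woman's in-window births by her age group at each birth.

    Returns ``(counts, n_dropped)``: a length-7 vector of births whose
    CMC falls in ``(interview - window_months, interview]`` with the
    mother aged [15, 50), plus the count of in-window births dropped for
    falling outside those ages.
    """
    counts = np.zeros(N_AGE_GROUPS, dtype=int)
    dropped = 0
    for b in birth_cmcs:
        if b <= dob_cmc:
            raise ValueError(f"birth CMC {b} not after mother's dob {dob_cmc}")
        if not interview_cmc - window_months < b <= interview_cmc:
            continue
        age = _age_months(b, dob_cmc)
        if _AGE_MIN <= age < _AGE_MAX:
            counts[(age - _AGE_MIN) // _WIDTH] += 1
        else:
            dropped += 1
    return counts, dropped


def build_person_year_table(
    women: pd.DataFrame,
    births: pd.DataFrame | None,
    window_months: int,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Convert woman-level records to long person-year rows.

    ``women`` needs columns woman_id, dob_cmc, interview_cmc; ``births``
    is the long file (woman_id, birth_cmc).  One row is emitted per
    (woman, contributed age group) - a woman is tallied once per group
    she touches, at most twice for windows up to five years - with
    columns woman_id, g, exposure_years, births, followed by the woman's
    ``covariates`` row (aligned on woman_id) when given.
    """
    birth_map: dict = {}
    if births is not None and len(births):
        birth_map = {
            wid: grp["birth_cmc"].to_numpy()
            for wid, grp in births.groupby("woman_id")
        }
    if covariates is not None and len(covariates) != len(women):
        raise ValueError("covariates must align row-for-row with women")

    rows = []
    cov_rows = []
    for pos, row in enumerate(women.itertuples(index=False)):
        wid = row.woman_id
        dob = int(row.dob_cmc)
        ivw = int(row.interview_cmc)
        segs = woman_exposure(dob, ivw, window_months)
        if not segs:
            continue
        counts, _ = allocate_births(birth_map.get(wid, ()), dob, ivw, window_months)
        for g, months in segs:
            rows.append((wid, g, months / 12.0, int(counts[g])))
            cov_rows.append(pos)
    table = pd.DataFrame(rows, columns=["woman_id", "g", "exposure_years", "births"])
    if covariates is not None:
        cov = covariates.iloc[cov_rows].reset_index(drop=True)
        table = pd.concat([table, cov], axis=1)
    return table


def aggregate(table: pd.DataFrame) -> ExposureTable:
    """Sum births and exposure by age group into an :class:`ExposureTable`."""
    if len(table) == 0:
        raise ValueError("empty person-year table")
    B = np.zeros(N_AGE_GROUPS)
    E = np.zeros(N_AGE_GROUPS)
    sums = table.groupby("g")[["births", "exposure_years"]].sum()
    for g, row in sums.iterrows():
        B[int(g)] = row["births"]
        E[int(g)] = row["exposure_years"]
    return ExposureTable(B=B, E=E)
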