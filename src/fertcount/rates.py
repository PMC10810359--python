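"""Fertility measures from aggregated births and exposure.

Given per-age-group totals of births B_g and woman-years of exposure
E_g (g = 0..6 for 15-19 ... 45-49):

* ASFR_g = 1000 B_g / E_g              (births per 1000 woman-years)
* TFR    = 5 * sum_g ASFR_g / 1000     (lifetime births per woman)
* GFR    = 1000 * sum B_g / sum E_g    (births per 1000 woman-years)
* GRR    = 5 * sum_g ASFR_g P_g / 1000 (lifetime daughters per woman)

P_g is the proportion of female births in group g, supplied by the user
(e.g. from an observed sex ratio); with P_g = 0.5 everywhere,
GRR = TFR / 2 exactly.  The TFR and GRR summations are reported per
woman (the per-1000 ASFRs are divided back by 1000), and the GFR
carries the per-1000 scaling its conventional magnitude (~100-200)
implies.  All measures assume no mortality over the reproductive span.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .exposure import N_AGE_GROUPS, ExposureTable


def asfr(B, E) -> np.ndarray:
    """Age-specific fertility rates, per 1000 woman-years of exposure.

    Groups with no exposure and no births return 0 (they are flagged by
    :func:`fertility_estimates`); births without exposure are an error.
    """
    B = np.asarray(B, dtype=float)
    E = np.asarray(E, dtype=float)
    if B.shape != (N_AGE_GROUPS,) or E.shape != (N_AGE_GROUPS,):
        raise ValueError("B and E must be length-7 vectors")
    if np.any((B > 0) & (E == 0)):
        raise ValueError("births recorded in a group with zero exposure")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(E > 0, 1000.0 * B / np.where(E > 0, E, 1.0), 0.0)
    return out


def tfr(asfr_vector) -> float:
    """Total fertility rate (births per woman): 5 * sum of group ASFRs / 1000."""
    v = np.asarray(asfr_vector, dtype=float)
    if v.shape != (N_AGE_GROUPS,):
        raise ValueError("ASFR vector must have length 7")
    return float(5.0 * v.sum() / 1000.0)


def gfr(B, E) -> float:
    """General fertility rate: 1000 * total births / total woman-years."""
    B = np.asarray(B, dtype=float)
    E = np.asarray(E, dtype=float)
    if E.sum() <= 0:
        raise ValueError("total exposure must be positive")
    return float(1000.0 * B.sum() / E.sum())


def grr(asfr_vector, p_female) -> float:
    """Gross reproduction rate (daughters per woman).

    ``p_female`` is a scalar or length-7 vector of female-birth
    proportions P_g.
    """
    v = np.asarray(asfr_vector, dtype=float)
    P = np.broadcast_to(np.asarray(p_female, dtype=float), v.shape).copy()
    if np.any((P < 0) | (P > 1)):
        raise ValueError("p_female proportions must lie in [0, 1]")
    return float(5.0 * (v * P).sum() / 1000.0)


@dataclasses.dataclass
class FertilityEstimates:
    """ASFR vector plus the three summary fertility measures."""

    asfr: np.ndarray  # per 1000 woman-years, length 7
    tfr: float  # births per woman
    gfr: float  # births per 1000 woman-years
    grr: float  # daughters per woman
    p_female: np.ndarray  # length-7 P_g actually used
    empty_groups: tuple = ()  # groups with neither exposure nor births

    def as_dict(self) -> dict:
        d = {f"asfr_{g}": float(self.asfr[g]) for g in range(N_AGE_GROUPS)}
        d.update(tfr=self.tfr, gfr=self.gfr, grr=self.grr)
        return d


def fertility_estimates(table: ExposureTable, p_female=0.5) -> FertilityEstimates:
    """All four measures from an aggregated births/exposure table."""
    a = asfr(table.B, table.E)
    P = np.broadcast_to(np.asarray(p_female, dtype=float), a.shape).copy()
    empty = tuple(
        int(g)
        for g in range(N_AGE_GROUPS)
        if table.E[g] == 0 and table.B[g] == 0
    )
    return FertilityEstimates(
        asfr=a,
        tfr=tfr(a),
        gfr=gfr(table.B, table.E),
        grr=grr(a, P),
        p_female=P,
        empty_groups=empty,
    )
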