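"""Century-month-code (CMC) date arithmetic.

DHS surveys encode dates as months elapsed since January 1900
(January 1900 = 1).  All exposure and birth-history arithmetic in this
package is done at month resolution on this scale.
"""

from __future__ import annotations


def cmc_from_date(year: int, month: int) -> int:
    """Convert a calendar (year, month) to a century month code.

    CMC = 12 * (year - 1900) + month, so (1900, 1) -> 1 and
    (2017, 12) -> 1416.
    """
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    if year < 1900:
        raise ValueError(f"year must be >= 1900, got {year}")
    return 12 * (year - 1900) + month


def date_from_cmc(cmc: int) -> tuple[int, int]:
    """Inverse of :func:`cmc_from_date`: CMC -> (year, month)."""
    if cmc < 1:
        raise ValueError(f"CMC must be >= 1, got {cmc}")
    year, month0 = divmod(cmc - 1, 12)
    return 1900 + year, month0 + 1
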