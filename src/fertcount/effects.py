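"""Effect-interpretation arithmetic for log-linear count regressions.

Coefficients on the log-mean scale are translated into the quantities
an analyst actually reports: relative rates exp(beta), rate ratios
between two categories exp(beta_a - beta_b), percentage changes
100 (exp(beta * delta) - 1) for a delta-unit covariate shift, Wald
confidence intervals and their exponentiated counterparts, and the
conventional significance-code strings.
"""

from __future__ import annotations

import math

#: z multiplier per confidence level, fixed at the two-decimal values
#: used in conventional reporting (1.96 for 95%).
_Z_TABLE = {0.90: 1.645, 0.95: 1.96, 0.99: 2.576}


def relative_rate(beta_j: float) -> float:
    """Multiplicative effect exp(beta_j) of a one-unit (or dummy) shift."""
    return math.exp(beta_j)


def rate_ratio(beta_a: float, beta_b: float) -> float:
    """Rate for category a relative to category b: exp(beta_a - beta_b)."""
    return math.exp(beta_a - beta_b)


def pct_change(beta: float, delta: float = 1.0) -> float:
    """Percent change in the expected count for a ``delta``-unit shift.

    100 * (exp(beta * delta) - 1); negative values are declines.
    """
    return 100.0 * (math.exp(beta * delta) - 1.0)


def wald_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Wald interval beta +/- z * se (z = 1.96 at the 95% level)."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    from scipy.stats import norm

    z = _Z_TABLE.get(round(level, 2), float(norm.ppf(0.5 + level / 2)))
    return beta - z * se, beta + z * se


def exp_ci(lo: float, hi: float) -> tuple[float, float]:
    """Map interval endpoints through exp (CI for the relative rate)."""
    return math.exp(lo), math.exp(hi)


def significance_code(p: float) -> str:
    """Conventional star codes: 0 '***' 0.001 '**' 0.01 '*' 0.05 '.' 0.1 ' ' 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return " "
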