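"""Per-site effect sizes: Hedges' d for space use, log response ratio for
nocturnality, with sampling variances and back-transforms.

Sign conventions
----------------
Both estimators subtract/divide so that **negative values mean avoidance of
high disturbance**: d < 0 when space use is lower in the high-disturbance
group, and RR = ln(p_low / p_high) < 0 when nocturnality is higher in the
high-disturbance group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


class DegenerateVarianceError(ValueError):
    """Raised when a variance formula is undefined (zero SD, boundary p)."""


@dataclass
class EffectSize:
    """One site-level effect estimate with its sampling variance.

    ``response`` is ``"spatial"`` (Hedges' d over sample units) or
    ``"temporal"`` (log response ratio of nocturnal proportions).  Group
    sizes are numbers of sample units for spatial effects and numbers of
    active observations for temporal effects.
    """

    site_id: str
    response: str
    estimate: float
    variance: float
    n_low: int
    n_high: int
    p_low: Optional[float] = None
    p_high: Optional[float] = None

    def __post_init__(self):
        if self.response not in ("spatial", "temporal"):
            raise ValueError(f"unknown response type {self.response!r}")
        if not self.variance > 0:
            raise ValueError("variance must be strictly positive")


def small_sample_correction(n_low: int, n_high: int) -> float:
    """Hedges' small-sample bias factor J = 1 - 3/(4m - 1), m = n1+n2-2."""
    m = n_low + n_high - 2
    return 1.0 - 3.0 / (4.0 * m - 1.0)


def hedges_d(mean_low: float, sd_low: float, n_low: int,
             mean_high: float, sd_high: float, n_high: int) -> tuple[float, float]:
    """Bias-corrected standardized mean difference (high minus low).

    Returns ``(d, variance)`` with
    ``d = J * (mean_high - mean_low) / s_pooled`` and
    ``variance = 1/n_low + 1/n_high + d^2 / (2 (n_low + n_high))``,
    where ``s_pooled`` is the (n-1)-weighted pooled SD and J the
    small-sample correction.
    """
    if n_low < 2 or n_high < 2:
        raise ValueError("each group needs at least 2 sample units")
    s2_pooled = ((n_low - 1) * sd_low ** 2 + (n_high - 1) * sd_high ** 2) / (
        n_low + n_high - 2)
    if not s2_pooled > 0:
        raise DegenerateVarianceError("pooled SD is zero; d is undefined")
    d = small_sample_correction(n_low, n_high) * (mean_high - mean_low) / np.sqrt(
        s2_pooled)
    variance = 1.0 / n_low + 1.0 / n_high + d * d / (2.0 * (n_low + n_high))
    return float(d), float(variance)


def log_response_ratio(p_low: float, n_low: int,
                       p_high: float, n_high: int) -> tuple[float, float]:
    """Log ratio of nocturnal proportions, RR = ln(p_low / p_high).

    The variance follows the delta-method formula for a ratio of binomial
    proportions::

        Var = (1 - p_low) / (n_low p_low) + (1 - p_high) / (n_high p_high)

    Boundary proportions (0 or 1) make the variance undefined and raise;
    no continuity correction is applied silently.
    """
    if n_low < 1 or n_high < 1:
        raise ValueError("group sizes must be >= 1")
    for name, p in (("p_low", p_low), ("p_high", p_high)):
        if not 0.0 < p < 1.0:
            raise DegenerateVarianceError(
                f"{name}={p} is on the boundary; RR variance undefined")
    rr = float(np.log(p_low / p_high))
    variance = (1.0 - p_low) / (n_low * p_low) + (1.0 - p_high) / (n_high * p_high)
    return rr, float(variance)


def percent_nocturnality_shift(rr: float) -> float:
    """Back-transform an RR to the percent increase in nocturnality.

    Returns ``(exp(-rr) - 1) * 100``: the percent by which the nocturnal
    proportion under high disturbance exceeds that under low disturbance.
    """
    if not np.isfinite(rr):
        raise ValueError("rr must be finite")
    return float((np.exp(-rr) - 1.0) * 100.0)
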