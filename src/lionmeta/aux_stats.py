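"""Side analyses: OLS of spatial on temporal effects, one-way ANOVA and
linear models for study characteristics, Dixon's Q outlier test, and a
two-sample t-test power helper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats


@dataclass
class SimpleFitResult:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    f_stat: float
    df1: int
    df2: int
    p_value: float


def simple_linear(y, x) -> SimpleFitResult:
    """Unweighted OLS of y on x with the F-test of the slope."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return SimpleFitResult(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        slope_se=float(res.bse[1]), intercept_se=float(res.bse[0]),
        r_squared=float(res.rsquared), f_stat=float(res.fvalue),
        df1=int(res.df_model), df2=int(res.df_resid),
        p_value=float(res.f_pvalue))


def oneway_anova(values, group_labels) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA: returns (F, df1, df2, p)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups = []
    for g in pd_unique(labels):
        sub = values[labels == g]
        if sub.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        groups.append(sub)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = values.size - len(groups)
    return float(f), df1, df2, float(p)


def pd_unique(arr):
    """Unique values preserving first-appearance order."""
    seen, out = set(), []
    for v in arr:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


# Dixon ratio variants: (numerator gap order, denominator trim) by n.
# r10: (x2-x1)/(xn-x1); r11: (x2-x1)/(x(n-1)-x1);
# r21: (x3-x1)/(x(n-1)-x1); r22: (x3-x1)/(x(n-2)-x1).
_DIXON_VARIANTS = [
    (3, 7, 1, 0, "r10"),
    (8, 10, 1, 1, "r11"),
    (11, 13, 2, 1, "r21"),
    (14, 30, 2, 2, "r22"),
]


def _dixon_ratio(sorted_vals: np.ndarray, gap: int, trim: int) -> tuple[float, float]:
    """Dixon ratios for the lowest and highest value of a sorted sample."""
    n = sorted_vals.shape[-1]
    span_low = sorted_vals[..., n - 1 - trim] - sorted_vals[..., 0]
    span_high = sorted_vals[..., n - 1] - sorted_vals[..., trim]
    with np.errstate(divide="ignore", invalid="ignore"):
        q_low = (sorted_vals[..., gap] - sorted_vals[..., 0]) / span_low
        q_high = (sorted_vals[..., n - 1] - sorted_vals[..., n - 1 - gap]) / span_high
    return q_low, q_high


def dixon_q(values, n_mc: int = 100_000, seed: int = 0
            ) -> tuple[float, float, int]:
    """Dixon's Q test for a single outlier (two-sided).

    The ratio variant follows sample size (r10 for n=3-7, r11 for 8-10,
    r21 for 11-13, r22 for 14-30); the statistic is the larger of the
    low-end and high-end ratios.  The p-value is Monte-Carlo, from the
    null distribution of the same statistic over standard-normal samples
    (``n_mc`` replicates, seeded).  Returns (Q, p, index of the flagged
    value in the input).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    variant = next(((g, t) for lo, hi, g, t, _ in _DIXON_VARIANTS
                    if lo <= n <= hi), None)
    if variant is None:
        raise ValueError(f"Dixon's test supports 3 <= n <= 30, got {n}")
    gap, trim = variant
    order = np.argsort(values)
    q_low, q_high = _dixon_ratio(values[order], gap, trim)
    if q_high >= q_low:
        q, flagged = float(q_high), int(order[-1])
    else:
        q, flagged = float(q_low), int(order[0])

    rng = np.random.default_rng(seed)
    sims = np.sort(rng.standard_normal((n_mc, n)), axis=1)
    s_low, s_high = _dixon_ratio(sims, gap, trim)
    null = np.maximum(s_low, s_high)
    p = float((np.count_nonzero(null >= q) + 1) / (n_mc + 1))
    return q, p, flagged


def ttest_power_n(d: float, alpha: float = 0.05, power: float = 0.80,
                  n_max: int = 100_000) -> int:
    """Smallest per-group n giving the target power for a two-sided,
    two-sample t-test at effect size d, via the noncentral t distribution.
    """
    if not d > 0:
        raise ValueError("effect size d must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        ncp = d * np.sqrt(n / 2.0)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        achieved = (stats.nct.sf(tcrit, df, ncp)
                    + stats.nct.cdf(-tcrit, df, ncp))
        if achieved >= power:
            return n
    raise RuntimeError("power target not reached within n_max")
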