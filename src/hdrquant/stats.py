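"""Condition comparisons: fold changes, Student's t-tests and OLS regression.

Fold changes between condition means are reported to two significant
figures.  Group comparisons use the two-tailed Student's (pooled,
equal-variance) t-test with ``df = n_a + n_b - 2`` and the figure-legend
significance bands: ``*`` for 0.01 < p < 0.05, ``**`` for 0.001 < p < 0.01,
``***`` below that, ``ns`` at p >= 0.05.  No multiple-testing correction is
applied (per-comparison reporting).  Linear regression (HDR % on indel %)
is ordinary least squares with the two-tailed p-value for slope != 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "RegressionResult",
    "fold_change",
    "to_sig_figs",
    "significance_band",
    "two_sample_t_test",
    "linear_regression",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComparisonResult:
    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    fold_change: float
    t_statistic: float
    p_value: float
    significant: bool  # p < 0.05
    significance_band: str  # 'ns' | '*' | '**' | '***'


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def fold_change(numerator: float, denominator: float) -> float:
    """Ratio of two positive quantities (report with :func:`to_sig_figs`)."""
    if denominator <= 0:
        raise ValueError(f"fold change denominator must be positive, got {denominator}")
    if numerator <= 0:
        raise ValueError(f"fold change numerator must be positive, got {numerator}")
    return numerator / denominator


def to_sig_figs(x: float, figures: int = 2) -> float:
    """Round to the given number of significant figures (prose convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, figures - 1 - math.floor(math.log10(abs(x))))


def significance_band(p_value: float) -> str:
    if p_value >= 0.05:
        return "ns"
    if p_value >= 0.01:
        return "*"
    if p_value >= 0.001:
        return "**"
    return "***"


def two_sample_t_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
) -> ComparisonResult:
    """Two-tailed Student's t-test (pooled variance, df = n_a + n_b − 2).

    Degenerate zero-variance inputs: equal means give t = 0, p = 1; unequal
    means give p = 0 (logged).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            logger.warning(
                "zero pooled variance with unequal means (%s vs %s); p set to 0",
                label_a,
                label_b,
            )
            t = math.copysign(math.inf, a.mean() - b.mean())
            p = 0.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=True)
        t, p = float(t), float(p)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    fold = (
        fold_change(mean_a, mean_b)
        if mean_a > 0 and mean_b > 0
        else math.nan
    )
    return ComparisonResult(
        label_a,
        label_b,
        mean_a,
        mean_b,
        fold,
        t,
        p,
        significant=p < 0.05,
        significance_band=significance_band(p),
    )


def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with the two-tailed slope p-value.

    ``r_squared`` is the squared Pearson correlation.  Requires n >= 3 and
    non-constant x.
    """
    xs = np.asarray(x, dtype=float)
    ys = np.asarray(y, dtype=float)
    if xs.size != ys.size:
        raise ValueError("x and y must have equal length")
    if xs.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(xs) == 0.0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(xs, ys)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        p_value=float(res.pvalue),
    )
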