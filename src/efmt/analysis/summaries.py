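"""Summary-statistic inference: contrasts, t-tests, correlations, effect sizes.

These operate on printed or computed summary numbers (means, SDs, SEs, r's)
exactly as a trial report does, so published tables can be checked row by row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SummaryTTest",
    "CorrelationResult",
    "contrast_t_p",
    "percent_reduction",
    "pooled_t_from_summary",
    "corr_with_p",
    "corr_p_from_summary",
    "cohens_d_from_summary",
]


@dataclass(frozen=True)
class SummaryTTest:
    """Two-sample pooled-variance t-test computed from summary statistics."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t: float
    df: int
    p: float


def contrast_t_p(difference: float, se: float, df: int) -> tuple[float, float]:
    """t and two-sided p for a least-squares-mean difference given its SE/df."""
    if se <= 0:
        raise ValueError("se must be > 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    t = difference / se
    return float(t), float(2 * stats.t.sf(abs(t), df))


def percent_reduction(baseline_mean: float, outcome_mean: float) -> float:
    """Percent reduction from baseline, 100 * (baseline - outcome) / baseline."""
    if baseline_mean <= 0:
        raise ValueError("baseline_mean must be > 0")
    return 100.0 * (baseline_mean - outcome_mean) / baseline_mean


def pooled_t_from_summary(m1: float, sd1: float, n1: int,
                          m2: float, sd2: float, n2: int) -> SummaryTTest:
    """Two-sample pooled-variance t with df = n1 + n2 - 2 from group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    if sp2 == 0:
        t = 0.0 if m1 == m2 else np.inf * np.sign(m1 - m2)
    else:
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return SummaryTTest(m1, sd1, n1, m2, sd2, n2, float(t), df, p)


def corr_with_p(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with the two-sided p from the t transform at n - 2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return corr_p_from_summary(r, n)


def corr_p_from_summary(r: float, n: int) -> CorrelationResult:
    """p for a printed (r, n) pair via t = r*sqrt(n-2)/sqrt(1-r^2)."""
    if not (-1.0 <= r <= 1.0):
        raise ValueError("r must lie in [-1, 1]")
    if n < 3:
        raise ValueError("need n >= 3")
    df = n - 2
    if abs(r) == 1.0:
        return CorrelationResult(r, n, float(np.sign(r) * np.inf), df, 0.0)
    t = r * np.sqrt(df) / np.sqrt(1 - r * r)
    return CorrelationResult(float(r), n, float(t), df, float(2 * stats.t.sf(abs(t), df)))


def cohens_d_from_summary(m1: float, sd1: float, n1: int,
                          m2: float, sd2: float, n2: int) -> float:
    """Standardized mean difference (m1 - m2) / pooled SD."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    return float((m1 - m2) / np.sqrt(sp2))
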