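"""Standardized major axis (SMA) regression, correlation tests and the
paired Wilcoxon signed-rank comparison.

SMA (reduced major axis) is the symmetric line-fitting method standard for
trait allometry: slope = sign(r) * s_y / s_x, so neither variable is treated
as the predictor and refitting y-on-x vs x-on-y gives reciprocal slopes.
Significance of an SMA relationship is the test of r = 0 (the SMA slope
itself is undefined under independence, since its magnitude s_y/s_x does not
shrink with r).

Regressions on phylogenetically independent contrasts are forced through the
origin with the x-contrasts positivized (each contrast pair's sign flipped
so the x-contrast is non-negative) — the standard contrast convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "SMAFit",
    "PairedComparison",
    "sma_fit",
    "sma_fit_origin",
    "pearson_r",
    "wilcoxon_signed_rank",
]


@dataclass
class SMAFit:
    slope: float
    intercept: float | None
    r: float
    r_squared: float
    p_value: float
    n: int
    through_origin: bool


@dataclass
class PairedComparison:
    """Wilcoxon signed-rank comparison of paired trait values.

    ``differences`` holds the per-species (field - greenhouse) differences
    after dropping exact zeros; ``statistic`` is W, the sum of ranks of the
    positive differences.
    """

    differences: np.ndarray
    statistic: float
    p_value: float
    n: int
    median_difference: float
    direction: str
    method: str


def _validated_xy(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if len(x) < min_n:
        raise InsufficientDataError(f"need at least {min_n} observations, got {len(x)}")
    return x, y


def sma_fit(x, y) -> SMAFit:
    """Standardized major axis fit of y against x on species means.

    slope = sign(r) * s_y / s_x, intercept = mean(y) - slope * mean(x);
    the two-tailed p-value tests r = 0 via t = r sqrt((n-2)/(1-r^2)) on
    n - 2 degrees of freedom.
    """
    x, y = _validated_xy(x, y, 3)
    n = len(x)
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise DegenerateInputError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    sign = np.sign(r) if r != 0 else 1.0
    slope = float(sign * sy / sx)
    intercept = float(y.mean() - slope * x.mean())
    p = _r_test_p(r, df=n - 2)
    return SMAFit(
        slope=slope, intercept=intercept, r=r, r_squared=r * r,
        p_value=p, n=n, through_origin=False,
    )


def sma_fit_origin(xc, yc) -> SMAFit:
    """Through-origin SMA fit for phylogenetically independent contrasts.

    The x-contrasts are positivized first (sign of each contrast pair
    flipped so xc >= 0; |r| and |slope| are invariant to this).  Uncentered
    moments give r = sum(xy)/sqrt(sum(x^2) sum(y^2)) and slope =
    sign(r) sqrt(sum(y^2)/sum(x^2)); p uses n - 1 degrees of freedom since
    no intercept is estimated.
    """
    x, y = _validated_xy(xc, yc, 3)
    n = len(x)
    flip = np.where(x < 0, -1.0, 1.0)
    x, y = x * flip, y * flip
    sxx = float(np.sum(x * x))
    syy = float(np.sum(y * y))
    if sxx == 0 or syy == 0:
        raise DegenerateInputError("contrasts with zero sum of squares")
    sxy = float(np.sum(x * y))
    r = max(-1.0, min(1.0, sxy / np.sqrt(sxx * syy)))
    sign = np.sign(r) if r != 0 else 1.0
    slope = float(sign * np.sqrt(syy / sxx))
    p = _r_test_p(r, df=n - 1)
    return SMAFit(
        slope=slope, intercept=None, r=r, r_squared=r * r,
        p_value=p, n=n, through_origin=True,
    )


def _r_test_p(r: float, df: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, df))


def pearson_r(x, y) -> tuple[float, float, int]:
    """Product-moment correlation with a two-tailed p-value.

    Requires n >= 4 so that the Fisher-z variance 1/(n-3) downstream is
    defined; smaller samples are rejected rather than silently pooled.
    """
    x, y = _validated_xy(x, y, 4)
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), len(x)


def _signed_rank_null_tail(doubled_ranks: np.ndarray, w2: int) -> tuple[float, float]:
    """P(W2 <= w2) and P(W2 >= w2) for the exact signed-rank null.

    ``doubled_ranks`` are the tie-averaged ranks times two (integers), so
    the distribution of the doubled positive-rank sum W2 over all 2^n
    equiprobable sign patterns can be built by dynamic programming — an
    exact enumeration without iterating the 2^n patterns explicitly.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for dr in doubled_ranks:
        shifted = np.zeros_like(counts)
        shifted[dr:] = counts[: total + 1 - dr]
        counts = counts + shifted
    counts /= counts.sum()
    return float(counts[: w2 + 1].sum()), float(counts[w2:].sum())


def wilcoxon_signed_rank(greenhouse, field, exact_limit: int = 25) -> PairedComparison:
    """Paired Wilcoxon signed-rank test of field vs greenhouse trait values.

    Zero differences are dropped (classic Wilcoxon); tied absolute
    differences receive average ranks.  The two-tailed p-value is exact (by
    enumeration of the sign-pattern null) for n <= ``exact_limit`` and uses
    the normal approximation with continuity and tie corrections above that.
    Fewer than 5 nonzero differences gives a warning: no p-value below 1/16
    is attainable.
    """
    g = np.asarray(greenhouse, dtype=float)
    f = np.asarray(field, dtype=float)
    if g.shape != f.shape or g.ndim != 1:
        raise ValueError("paired samples must be 1-d arrays of equal length")
    d = f - g
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    if n < 5:
        warnings.warn(f"only {n} nonzero differences; signed-rank p is coarse")
    ranks = stats.rankdata(np.abs(d))
    w = float(np.sum(ranks[d > 0]))
    if n <= exact_limit:
        doubled = np.rint(2 * ranks).astype(int)
        w2 = int(round(2 * w))
        lo, hi = _signed_rank_null_tail(doubled, w2)
        p = min(1.0, 2.0 * min(lo, hi))
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
            tie_counts**3 - tie_counts
        ) / 48.0
        diff = w - mean
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "normal-approximation"
    med = float(np.median(d))
    direction = "positive" if med > 0 else "negative" if med < 0 else "mixed"
    return PairedComparison(
        differences=d, statistic=w, p_value=min(1.0, p), n=n,
        median_difference=med, direction=direction, method=method,
    )
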