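"""Affinity arithmetic and volume-affinity regression.

The binding data motivate a nonmonotone size-affinity picture (the '55%'
occupancy argument from supramolecular chemistry): affinity rises with
substituent volume up to an optimum and falls beyond it.  Two models capture
this: a two-segment ('ascending/descending') piecewise-linear fit with the
breakpoint found by exhaustive search, and an ordinary quadratic fit whose
interior vertex plays the same role.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ValidationError

__all__ = [
    "QuadraticFit",
    "TwoSegmentFit",
    "correlate",
    "fold_ratio",
    "quadratic_fit",
    "two_segment_fit",
]


def fold_ratio(ic50_a: float, ic50_b: float) -> float:
    """Affinity fold change a/b between two IC50 values (same units)."""
    if not (ic50_a > 0 and ic50_b > 0):
        raise ValidationError("IC50 values must be positive")
    return ic50_a / ic50_b


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and SSE of y ~ x."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(resid @ resid)


@dataclass(frozen=True)
class TwoSegmentFit:
    breakpoint: float
    ascending_slope: float
    ascending_intercept: float
    descending_slope: float
    descending_intercept: float
    r_ascending: float
    r_descending: float
    sse: float
    n: int
    #: True when no breakpoint improved on a single line (collinear data);
    #: the single line is then reported in the ascending fields.
    single_line: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.single_line:
            return self.ascending_slope * x + self.ascending_intercept
        left = self.ascending_slope * x + self.ascending_intercept
        right = self.descending_slope * x + self.descending_intercept
        return np.where(x < self.breakpoint, left, right)


def two_segment_fit(x, y) -> TwoSegmentFit:
    """Fit two least-squares lines split at the breakpoint minimising total SSE.

    Candidate breakpoints are the midpoints between consecutive distinct
    ``x`` values that leave at least two points on each side; ties break
    toward the smaller breakpoint.  When the best split fails to produce a
    genuine ascending/descending pair (or never beats a single line within
    round-off) the single-line least-squares fit is reported instead, with
    ``single_line=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-d arrays")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValidationError("two-segment fit needs at least 4 points")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    xu = np.unique(xs)

    slope1, icpt1, sse1 = _ols_line(xs, ys)
    best = None
    for lo, hi in zip(xu, xu[1:]):
        bp = 0.5 * (lo + hi)
        left = xs < bp
        if left.sum() < 2 or (~left).sum() < 2:
            continue
        sl, il, el = _ols_line(xs[left], ys[left])
        sr, ir, er = _ols_line(xs[~left], ys[~left])
        sse = el + er
        if best is None or sse < best[0] - 1e-12:
            best = (sse, bp, (sl, il), (sr, ir), left)
    if best is None:
        raise ValidationError("no admissible breakpoint with >=2 points per side")

    sse, bp, (sl, il), (sr, ir), left = best
    degenerate = not (sl > 0 and sr < 0)
    if degenerate and sse1 <= sse + 1e-9:
        return TwoSegmentFit(
            breakpoint=math.nan,
            ascending_slope=slope1,
            ascending_intercept=icpt1,
            descending_slope=math.nan,
            descending_intercept=math.nan,
            r_ascending=_pearson(xs, ys),
            r_descending=math.nan,
            sse=sse1,
            n=int(x.size),
            single_line=True,
        )
    return TwoSegmentFit(
        breakpoint=float(bp),
        ascending_slope=sl,
        ascending_intercept=il,
        descending_slope=sr,
        descending_intercept=ir,
        r_ascending=_pearson(xs[left], ys[left]),
        r_descending=_pearson(xs[~left], ys[~left]),
        sse=float(sse),
        n=int(x.size),
        single_line=False,
    )


@dataclass(frozen=True)
class QuadraticFit:
    a: float
    b: float
    c: float
    r: float
    vertex: float
    n: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * x * x + self.b * x + self.c


def quadratic_fit(x, y) -> QuadraticFit:
    """Ordinary least squares of y on (1, x, x^2).

    ``r`` is the Pearson correlation between fitted and observed values (the
    convention used when a 'perfect R' is quoted for a curved fit); it is NaN
    when the observed y has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if np.unique(x).size < 3:
        raise ValidationError("quadratic fit needs at least 3 distinct x values")
    a, b, c = np.polyfit(x, y, 2)
    fitted = a * x * x + b * x + c
    r = _pearson(fitted, y)
    vertex = math.nan if a == 0 else float(-b / (2 * a))
    return QuadraticFit(float(a), float(b), float(c), r, vertex, int(x.size))


def correlate(x, y) -> tuple[float, int]:
    """Pearson R between two descriptor columns with listwise deletion of
    missing values; returns (R, n after deletion).  R is NaN when either
    column has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("columns must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("correlation needs n >= 3 after deletion")
    return _pearson(x, y), int(x.size)
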