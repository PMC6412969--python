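"""Optimal-score selection over snapshot pools, score-experiment correlation,
and linear reweighting of scoring-function components.

Third-party scoring functions are consumed as exported tables, never
re-implemented: each row carries the per-snapshot total and named component
values for one (derivative, function).  Whether 'optimal' means the maximum
or the minimum is a per-function declaration, part of the table's metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

__all__ = [
    "ReweightResult",
    "external_validate",
    "optimal_score",
    "optimal_score_table",
    "reweight_components",
    "score_affinity_correlation",
]

SCORE_TABLE_COLUMNS = ("derivative_id", "replica", "time_ns", "function", "total")


def _check_score_table(table: pd.DataFrame) -> None:
    missing = [c for c in SCORE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"score table lacks columns {missing}")


def optimal_score(
    table: pd.DataFrame,
    derivative: str,
    function: str,
    directions: Mapping[str, str],
    aggregate: str = "optimal",
) -> float:
    """Best (or mean) per-snapshot total for one derivative and function.

    ``directions`` maps function name to 'maximize' or 'minimize'; with
    ``aggregate='mean'`` the pool average is returned instead of the optimum.
    """
    _check_score_table(table)
    if function not in directions:
        raise ValidationError(f"no direction declared for function {function!r}")
    sub = table[
        (table["derivative_id"] == derivative) & (table["function"] == function)
    ]
    if len(sub) == 0:
        raise ValidationError(
            f"no score rows for ({derivative}, {function})"
        )
    totals = sub["total"].to_numpy(dtype=float)
    if aggregate == "mean":
        return float(totals.mean())
    if aggregate != "optimal":
        raise ValidationError(f"unknown aggregate {aggregate!r}")
    direction = directions[function]
    if direction == "maximize":
        return float(totals.max())
    if direction == "minimize":
        return float(totals.min())
    raise ValidationError(f"unknown direction {direction!r}")


def optimal_score_table(
    table: pd.DataFrame,
    directions: Mapping[str, str],
    aggregate: str = "optimal",
) -> pd.DataFrame:
    """Optimal (or mean) score for every (derivative, function) pair."""
    _check_score_table(table)
    rows = []
    for (did, fn), _ in table.groupby(["derivative_id", "function"]):
        rows.append(
            {
                "derivative_id": did,
                "function": fn,
                "score": optimal_score(table, did, fn, directions, aggregate),
            }
        )
    return pd.DataFrame(rows)


def score_affinity_correlation(
    scores: Mapping[str, float] | pd.Series,
    pic50: Mapping[str, float] | pd.Series,
    exclude: Sequence[str] = (),
) -> tuple[float, int]:
    """Pearson R between per-derivative scores and experimental pIC50.

    Compounds named in ``exclude`` (chiral mixtures, censored entries,
    declared outliers) are dropped, as are pairs with a missing value; the
    returned ``n`` reflects the pairs actually used.
    """
    scores = pd.Series(scores, dtype=float)
    pic50 = pd.Series(pic50, dtype=float)
    common = scores.index.intersection(pic50.index).difference(pd.Index(exclude))
    x = scores.loc[common].to_numpy()
    y = pic50.loc[common].to_numpy()
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("correlation needs n >= 3 after exclusions")
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan, int(x.size)
    return float(stats.pearsonr(x, y).statistic), int(x.size)


@dataclass(frozen=True)
class ReweightResult:
    component_names: tuple[str, ...]
    weights: np.ndarray = field(repr=False)
    intercept: float
    internal_r: float
    n: int

    def predict(self, components: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.component_names if c not in components.columns]
        if missing:
            raise ValidationError(f"validation table lacks components {missing}")
        x = components[list(self.component_names)].to_numpy(dtype=float)
        return x @ self.weights + self.intercept


def _collinear_columns(x: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that are (near-)linear combinations of the preceding ones."""
    bad = []
    for j in range(x.shape[1]):
        block = np.column_stack([np.ones(x.shape[0]), x[:, :j]])
        beta, *_ = np.linalg.lstsq(block, x[:, j], rcond=None)
        resid = x[:, j] - block @ beta
        scale = max(1.0, float(np.abs(x[:, j]).max()))
        if np.linalg.norm(resid) < 1e-8 * scale * math.sqrt(x.shape[0]):
            bad.append(names[j])
    return bad


def reweight_components(
    components: pd.DataFrame,
    pic50: Sequence[float] | pd.Series,
    component_names: Sequence[str] | None = None,
) -> ReweightResult:
    """Ordinary least squares of pIC50 on named score components.

    Returns the fitted weights plus intercept and the internal (training)
    Pearson R between fitted and observed pIC50.  Rank-deficient component
    matrices are rejected with the offending (collinear) columns named.
    """
    names = tuple(component_names or [c for c in components.columns])
    if len(names) < 1:
        raise ValidationError("at least one component required")
    x = components[list(names)].to_numpy(dtype=float)
    y = np.asarray(pic50, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValidationError("component matrix and pIC50 length mismatch")
    n, k = x.shape
    if n <= k + 1:
        raise ValidationError(
            f"need more observations ({n}) than components + 1 ({k + 1})"
        )
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < k + 1:
        bad = _collinear_columns(x, names)
        raise ValidationError(
            f"component matrix is rank deficient; collinear components: {bad}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    if np.std(fitted) == 0 or np.std(y) == 0:
        r = math.nan
    else:
        r = float(stats.pearsonr(fitted, y).statistic)
    return ReweightResult(
        component_names=names,
        weights=beta[1:],
        intercept=float(beta[0]),
        internal_r=r,
        n=n,
    )


def external_validate(
    result: ReweightResult,
    validation: pd.DataFrame,
    band: tuple[float, float],
) -> pd.DataFrame:
    """Classify validation compounds by whether the reweighted prediction
    falls inside a reference pIC50 band (e.g. 'similar affinity to the parent
    compound').

    ``validation`` needs a ``compound_id`` column plus every component the
    fit used.  Returns one row per compound with the prediction and a
    ``passed`` flag; the pass fraction is ``out['passed'].mean()``.
    """
    lo, hi = band
    if not lo <= hi:
        raise ValidationError("band must be (low, high) with low <= high")
    pred = result.predict(validation)
    return pd.DataFrame(
        {
            "compound_id": validation["compound_id"].to_numpy(),
            "predicted_pic50": pred,
            "passed": (pred >= lo) & (pred <= hi),
        }
    )
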