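"""Entropy weighting, TOPSIS and SAW over a decision matrix.

Alternatives are rows, criteria are columns, all entries strictly
positive.  Every criterion carries a direction: ``benefit`` (larger is
better) or ``cost``.

TOPSIS: vector-normalize each column to unit Euclidean norm, weight,
take the componentwise ideal-best/ideal-worst points (column max/min for
benefit criteria, reversed for cost), measure each alternative's
Euclidean separation from both ideals, and rank by the relative
closeness ``O' = L- / (L+ + L-)``.

SAW: normalize each benefit column by its maximum (cost columns by
min/x), then score ``G_k = sum_j w_j m_kj`` and rank descending.

Entropy weights: the information-content weighting that reproduces the
published weight table operates on the VECTOR-normalized matrix (unit
Euclidean column norms):

    E_j = -(1/ln m) * sum_i n_ij ln n_ij,   d_j = |1 - E_j|,
    w_j = d_j / sum_j d_j

with ``0 ln 0 := 0``.  Note that unit-norm columns are not probability
vectors, so E_j may exceed 1; the absolute divergence makes the weights
well defined either way, and this variant weights *low*-dispersion
columns more.  The conventional variant computed on sum-normalized
columns (``method='entropy-sum'``) is also provided; it does not
reproduce the published weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DecisionMatrix",
    "WeightVector",
    "TopsisResult",
    "SawResult",
    "vector_normalize",
    "entropy_weights",
    "topsis",
    "saw",
]


@dataclass(frozen=True)
class DecisionMatrix:
    """Positive alternatives-by-criteria matrix with per-criterion directions."""

    values: pd.DataFrame
    direction: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 1:
            raise ValueError("need at least 2 alternatives and 1 criterion")
        if not (v.to_numpy(dtype=float) > 0).all():
            raise ValueError("all decision-matrix entries must be strictly positive")
        dirs = {c: self.direction.get(c, "benefit") for c in v.columns}
        bad = [c for c, d in dirs.items() if d not in ("benefit", "cost")]
        if bad:
            raise ValueError(f"invalid direction for criteria {bad}")
        object.__setattr__(self, "direction", dirs)

    @property
    def alternatives(self) -> list[str]:
        return list(self.values.index)

    @property
    def criteria(self) -> list[str]:
        return list(self.values.columns)

    def is_benefit(self) -> np.ndarray:
        return np.array([self.direction[c] == "benefit" for c in self.criteria])


@dataclass(frozen=True)
class WeightVector:
    """Criterion weights summing to one."""

    w: pd.Series
    method: str = "user"

    def __post_init__(self) -> None:
        arr = self.w.to_numpy(dtype=float)
        if (arr <= 0).any():
            raise ValueError("weights must be positive")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {arr.sum()!r}")


@dataclass(frozen=True)
class TopsisResult:
    normalized: pd.DataFrame
    weighted: pd.DataFrame
    ideal_best: pd.Series
    ideal_worst: pd.Series
    separation_best: pd.Series
    separation_worst: pd.Series
    closeness: pd.Series
    rank: pd.Series


@dataclass(frozen=True)
class SawResult:
    normalized: pd.DataFrame
    weighted: pd.DataFrame
    score: pd.Series
    rank: pd.Series


def vector_normalize(d: DecisionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Scale every column to unit Euclidean norm."""
    v = d.values if isinstance(d, DecisionMatrix) else d
    arr = v.to_numpy(dtype=float)
    norms = np.sqrt((arr**2).sum(axis=0))
    return pd.DataFrame(arr / norms, index=v.index, columns=v.columns)


def entropy_weights(normalized: pd.DataFrame, method: str = "entropy-vector") -> WeightVector:
    """Information-content criterion weights from a normalized matrix.

    ``method='entropy-vector'`` expects the vector-normalized (unit
    Euclidean norm) matrix and is the variant that reproduces the
    published weights; ``'entropy-sum'`` renormalizes columns to sum to
    one first (the textbook construction).  Degenerate input where every
    column has zero divergence is an error.
    """
    arr = normalized.to_numpy(dtype=float)
    if (arr < 0).any() or (arr > 1 + 1e-12).any():
        raise ValueError("normalized entries must lie in [0, 1]")
    m = arr.shape[0]
    if method == "entropy-sum":
        arr = arr / arr.sum(axis=0)
    elif method != "entropy-vector":
        raise ValueError(f"unknown entropy method {method!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(arr > 0, arr * np.log(arr), 0.0)
    entropy = -plogp.sum(axis=0) / np.log(m)
    divergence = np.abs(1.0 - entropy)
    total = divergence.sum()
    if total <= 0:
        raise ValueError("all criteria have zero divergence; weights undefined")
    w = pd.Series(divergence / total, index=normalized.columns)
    return WeightVector(w=w, method=method)


def _ranks_desc(score: pd.Series) -> pd.Series:
    """Dense 1..m ranks, best (highest score) first; ties keep input order."""
    order = sorted(range(len(score)), key=lambda i: (-score.iloc[i], i))
    rank = pd.Series(0, index=score.index, dtype=int)
    for pos, i in enumerate(order, start=1):
        rank.iloc[i] = pos
    return rank


def topsis(d: DecisionMatrix, weights: WeightVector) -> TopsisResult:
    """Rank alternatives by relative closeness to the ideal point."""
    if list(weights.w.index) != d.criteria:
        raise ValueError("weight vector does not match decision-matrix criteria")
    n = vector_normalize(d)
    y = n * weights.w
    benefit = d.is_benefit()
    ymax, ymin = y.max(axis=0), y.min(axis=0)
    q_best = ymax.where(pd.Series(benefit, index=y.columns), ymin)
    q_worst = ymin.where(pd.Series(benefit, index=y.columns), ymax)
    l_best = np.sqrt(((y - q_best) ** 2).sum(axis=1))
    l_worst = np.sqrt(((y - q_worst) ** 2).sum(axis=1))
    denom = l_best + l_worst
    closeness = (l_worst / denom).where(denom > 0, 0.0)
    return TopsisResult(
        normalized=n,
        weighted=y,
        ideal_best=q_best,
        ideal_worst=q_worst,
        separation_best=l_best,
        separation_worst=l_worst,
        closeness=closeness,
        rank=_ranks_desc(closeness),
    )


def saw(d: DecisionMatrix, weights: WeightVector) -> SawResult:
    """Simple additive weighting: max-normalize, weight, sum, rank."""
    if list(weights.w.index) != d.criteria:
        raise ValueError("weight vector does not match decision-matrix criteria")
    v = d.values.astype(float)
    benefit = pd.Series(d.is_benefit(), index=v.columns)
    normalized = pd.DataFrame(
        {c: v[c] / v[c].max() if benefit[c] else v[c].min() / v[c] for c in v.columns},
        index=v.index,
    )[v.columns]
    weighted = normalized * weights.w
    score = weighted.sum(axis=1)
    return SawResult(normalized=normalized, weighted=weighted, score=score, rank=_ranks_desc(score))
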