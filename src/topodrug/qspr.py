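"""Quadratic structure-property (QSPR) regression.

Each physicochemical property P is modelled as a quadratic function of one
topological index TI:

    P = A + B * TI + C * TI**2

fitted by ordinary least squares.  Reported statistics: multiple
correlation R (the positive square root of R**2), R**2, adjusted R**2
(p = 2 predictors), the overall F statistic on (2, n-3) degrees of
freedom, its upper-tail probability, and RMSE = sqrt(SSE / n).

The solver orthogonalizes the design (SVD-backed least squares) rather
than forming normal equations: TI and TI**2 are near-collinear at the
magnitudes of molecular indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["QuadraticFit", "fit_quadratic", "predict", "correlation_table", "regression_table"]


@dataclass(frozen=True)
class QuadraticFit:
    """Least-squares quadratic model with its goodness-of-fit statistics."""

    A: float
    B: float
    C: float
    n: int
    R: float
    R2: float
    adjR2: float
    F: float
    RMSE: float
    p: float


def _design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, x * x])


def fit_quadratic(x, y) -> QuadraticFit:
    """Fit ``y = A + B x + C x**2`` by least squares.

    Requires ``n >= 4`` observations unless the fit is saturated (n = 3
    distinct points interpolate exactly; then F is reported as ``inf`` and
    p as 0).  At least three distinct x values are needed for the design
    to be full rank.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite inputs")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct x values (singular design)")

    X = _design(x)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValueError("singular design")
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    r2 = min(max(r2, 0.0), 1.0)
    if n > 3 and r2 < 1.0:
        f = (r2 / 2.0) / ((1.0 - r2) / (n - 3))
        p = float(stats.f.sf(f, 2, n - 3))
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 3)
    else:  # saturated or perfect fit
        f, p = math.inf, 0.0
        adj = 1.0
    return QuadraticFit(
        A=float(beta[0]),
        B=float(beta[1]),
        C=float(beta[2]),
        n=int(n),
        R=math.sqrt(r2),
        R2=r2,
        adjR2=adj,
        F=f,
        RMSE=math.sqrt(sse / n),
        p=p,
    )


def predict(fit: QuadraticFit, x) -> np.ndarray | float:
    """Evaluate the fitted quadratic at ``x``."""
    x = np.asarray(x, dtype=float)
    out = fit.A + fit.B * x + fit.C * x * x
    return float(out) if out.ndim == 0 else out


def regression_table(indices: pd.DataFrame, properties: pd.DataFrame) -> pd.DataFrame:
    """All index-by-property quadratic fits, one row per (index, property).

    Rows are aligned by name; the two tables must cover the same
    molecules.  Columns: n, A, B, C, R, R2, adjR2, F, RMSE, p.
    """
    if set(indices.index) != set(properties.index):
        raise ValueError("index table and property table cover different molecules")
    properties = properties.loc[indices.index]
    rows = []
    for ti in indices.columns:
        for prop in properties.columns:
            fit = fit_quadratic(indices[ti].to_numpy(), properties[prop].to_numpy())
            rows.append(
                {
                    "index": ti,
                    "property": prop,
                    "n": fit.n,
                    "A": fit.A,
                    "B": fit.B,
                    "C": fit.C,
                    "R": fit.R,
                    "R2": fit.R2,
                    "adjR2": fit.adjR2,
                    "F": fit.F,
                    "RMSE": fit.RMSE,
                    "p": fit.p,
                }
            )
    return pd.DataFrame(rows).set_index(["index", "property"])


def correlation_table(indices: pd.DataFrame, properties: pd.DataFrame) -> pd.DataFrame:
    """Matrix of multiple correlations R, indices as rows x properties as columns.

    Entry (i, j) is the R of the quadratic fit of property j on index i.
    The per-property argmax (strongest index for each property) is exposed
    through ``DataFrame.idxmax`` on the result.
    """
    reg = regression_table(indices, properties)
    return reg["R"].unstack("property").loc[list(indices.columns), list(properties.columns)]
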