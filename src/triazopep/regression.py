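"""Ordinary least squares with classical standard errors, plus exhaustive
best-subset search, for the structure–activity models.

The fits are plain OLS (normal equations, homoscedastic errors), the
method a spreadsheet regression produces: SE(β_j) = sqrt(σ̂²·[(XᵀX)⁻¹]_jj)
with σ̂² = RSS/(n−p−1).  The heavy lifting is delegated to statsmodels;
tests cross-check against an independent normal-equations oracle.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["LinearModelFit", "ols_fit", "predict", "best_subset",
           "CollinearityError"]


class CollinearityError(ValueError):
    """Design matrix is (numerically) rank deficient."""


@dataclass(frozen=True)
class LinearModelFit:
    """OLS fit summary.  ``params``/``bse`` are ordered (intercept, then
    the columns of X in input order)."""

    columns: Tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    r_squared: float
    adj_r_squared: float
    n: int
    residuals: np.ndarray

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    def coef(self, name: str) -> float:
        return float(self.params[1 + self.columns.index(name)])

    def se(self, name: str) -> float:
        return float(self.bse[1 + self.columns.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        names = ("intercept",) + self.columns
        return pd.DataFrame({"coef": self.params, "se": self.bse},
                            index=list(names))


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def ols_fit(X, y) -> LinearModelFit:
    """Fit y = β₀ + Xβ by ordinary least squares.

    ``X`` may be a DataFrame (column names are kept) or an array.  Refuses
    under-determined (n ≤ p+1) and exactly collinear designs, naming the
    dependent columns in the latter case.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(Xf):
        raise ValueError("y must be 1-D with one value per row of X")
    if np.isnan(y).any() or Xf.isna().any().any():
        raise ValueError("missing values in the regression inputs")
    n, p = Xf.shape
    if n <= p + 1:
        raise ValueError(f"need n > p+1 observations (n={n}, p={p})")
    design = np.column_stack([np.ones(n), Xf.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        dep = _dependent_columns(Xf)
        raise CollinearityError(
            f"collinear design; dependent columns: {dep}")
    res = sm.OLS(y, design).fit()
    return LinearModelFit(
        columns=tuple(map(str, Xf.columns)),
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        n=n,
        residuals=np.asarray(res.resid, dtype=float),
    )


def _dependent_columns(Xf: pd.DataFrame) -> List[str]:
    cols = list(map(str, Xf.columns))
    bad = []
    base = np.ones((len(Xf), 1))
    kept = base
    for name in cols:
        cand = np.column_stack([kept, Xf[name].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(name)
        else:
            kept = cand
    return bad


def predict(fit: LinearModelFit, X) -> np.ndarray:
    """ŷ = β₀ + Σ β_j x_j; X column names must match the fit."""
    Xf = _as_frame(X)
    if tuple(map(str, Xf.columns)) != fit.columns:
        raise ValueError(
            f"column mismatch: fit has {fit.columns}, "
            f"got {tuple(map(str, Xf.columns))}")
    return fit.intercept + Xf.to_numpy(dtype=float) @ fit.params[1:]


def best_subset(X_full, y, k_max: int) -> List[LinearModelFit]:
    """Fit every non-empty column subset of size ≤ k_max and rank by
    adjusted R² (ties broken by subset size, then by column order in
    ``X_full``, so results are deterministic).  Collinear subsets are
    skipped with a warning."""
    Xf = _as_frame(X_full)
    cols = list(Xf.columns)
    if not cols:
        raise ValueError("X_full has no columns")
    if k_max < 1 or k_max > len(cols):
        raise ValueError(f"k_max must be in 1..{len(cols)}")
    fits: List[Tuple[tuple, LinearModelFit]] = []
    for k in range(1, k_max + 1):
        for subset in itertools.combinations(range(len(cols)), k):
            sub = [cols[i] for i in subset]
            try:
                fit = ols_fit(Xf[sub], y)
            except (CollinearityError, ValueError) as exc:
                warnings.warn(f"subset {sub} skipped: {exc}")
                continue
            # round the criterion so affinely identical models (equal fit
            # up to float noise) tie and fall back to column order
            fits.append(((-round(fit.adj_r_squared, 10), len(subset),
                          subset), fit))
    fits.sort(key=lambda t: t[0])
    return [f for _, f in fits]
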