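"""Small shared linear-model helpers: design-matrix construction from a
covariate frame and plain OLS fits used across the association and
variance-explained stages."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = ["build_design", "ols_last_coefficient", "ols_r2", "orth_basis"]


def build_design(covariates, n_obs: int | None = None) -> np.ndarray:
    """Intercept + dummy-coded covariates as an (n, k) float design matrix.

    ``covariates`` may be None (intercept only; requires ``n_obs``), a
    DataFrame/Series, or a 2-D array. Non-numeric columns are dummy-coded
    with the first category (sorted) as reference.
    """
    if covariates is None:
        if n_obs is None:
            raise ValueError("n_obs required when covariates is None")
        return np.ones((n_obs, 1))
    if isinstance(covariates, pd.Series):
        covariates = covariates.to_frame()
    if isinstance(covariates, pd.DataFrame):
        cols = [np.ones(len(covariates))]
        for name in covariates.columns:
            col = covariates[name]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
            else:
                levels = sorted(col.astype(str).unique())
                for lev in levels[1:]:
                    cols.append((col.astype(str) == lev).to_numpy(dtype=float))
        return np.column_stack(cols)
    arr = np.asarray(covariates, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return np.column_stack([np.ones(arr.shape[0]), arr])


def orth_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of X (rank-revealing)."""
    return linalg.orth(np.asarray(X, dtype=float))


def ols_last_coefficient(y: np.ndarray, X: np.ndarray):
    """OLS of y on X; returns (beta, se, t, df, p) for the LAST column of X.

    Computed by residualising the last column on the others, which keeps the
    fit well-defined even when the nuisance block is rank deficient (e.g. a
    covariate level absent from a subset). Returns NaNs when the last column
    is collinear with the nuisance block or df <= 0.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    Q1 = orth_basis(X[:, :-1])
    x = X[:, -1]
    xres = x - Q1 @ (Q1.T @ x)
    norm = float(np.linalg.norm(xres))
    df = n - Q1.shape[1] - 1
    if norm <= 1e-8 * np.sqrt(n) or df <= 0:
        return np.nan, np.nan, np.nan, float(df), np.nan
    u = xres / norm
    proj = float(u @ y)
    yres = y - Q1 @ (Q1.T @ y)
    rss = max(float(yres @ yres) - proj**2, 0.0)
    beta = proj / norm
    sigma2 = rss / df
    if sigma2 == 0.0:
        return beta, 0.0, np.inf if beta != 0 else np.nan, float(df), 0.0
    se = float(np.sqrt(sigma2)) / norm
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta, se, t, float(df), float(p)


def ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Coefficient of determination of the OLS fit of y on X (X must contain
    an intercept column)."""
    y = np.asarray(y, dtype=float)
    beta, _, _, _ = np.linalg.lstsq(np.asarray(X, float), y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    return 1.0 - float(resid @ resid) / tss
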