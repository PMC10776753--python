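"""Vectorised covariate-adjusted group testing.

One QR factorisation of the shared design matrix serves every response
column, which is what makes epigenome-wide testing (tens of thousands of
CpGs) cheap. The group coefficient's Wald t and its two-sided p are
returned per column.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .errors import DegenerateResponseError, SingularDesignError

logger = logging.getLogger("imgomix")


def build_design(group: np.ndarray, covariates=None, covariate_names=None):
    """Intercept + group indicator + covariate columns.

    Returns (design, names) with the group column at index 1.
    """
    group = np.asarray(group, dtype=float)
    cols = [np.ones_like(group), group]
    names = ["intercept", "group"]
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
        if covariate_names is None:
            covariate_names = [f"cov{i}" for i in range(cov.shape[1])]
        names.extend(covariate_names)
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names):
    """Raise SingularDesignError naming the dependent columns."""
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = [names[i] for i in np.nonzero(diag <= tol)[0]]
    if bad:
        raise SingularDesignError(bad)


def mass_group_ttest(Y, group, covariates=None, covariate_names=None):
    """Wald t for the group indicator in ``y ~ 1 + group + covariates``.

    Parameters
    ----------
    Y : (n_subjects, m) array
        One response column per region / CpG. Rows with any NaN in the
        design are dropped listwise beforehand by the caller; NaNs in Y
        are not supported here.
    group : (n_subjects,) 0/1 indicator (1 = case).

    Returns
    -------
    dict with arrays ``t``, ``p``, ``coef`` (adjusted case-control
    difference), and scalar ``df``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    X, names = build_design(group, covariates, covariate_names)
    _check_rank(X, names)
    p_cols = X.shape[1]
    if n <= p_cols:
        raise SingularDesignError(["<too few subjects for design>"])

    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ Y)  # (p_cols, m)
    resid = Y - X @ beta
    df = n - p_cols
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    Rinv = np.linalg.inv(R)
    xtx_inv_diag = np.einsum("ij,ij->i", Rinv, Rinv)  # diag of (X'X)^-1
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv_diag[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, np.nan)
    if np.isnan(t).any():
        raise DegenerateResponseError(
            f"{int(np.isnan(t).sum())} response columns have zero residual variance"
        )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return {"t": t, "p": p, "coef": beta[1], "df": df}


def listwise_complete(subjects_df, columns):
    """Boolean mask of rows with finite values in ``columns``; logs drops."""
    sub = subjects_df[list(columns)].apply(lambda c: np.isfinite(c.astype(float)))
    mask = sub.all(axis=1).to_numpy()
    n_drop = int((~mask).sum())
    if n_drop:
        logger.info("listwise deletion dropped %d subjects with missing covariates", n_drop)
    return mask
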