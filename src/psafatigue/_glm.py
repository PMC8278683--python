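"""Minimal dense OLS / logistic fitters used in resampling loops.

Bootstrap and simulation studies in this package refit the mediator and
outcome regressions hundreds of thousands of times; these routines solve
the same maximum-likelihood problems as the general-purpose packages but
without per-fit object construction overhead. Their estimates are checked
against statsmodels in the test suite to ~1e-8.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ols_fit", "logit_fit", "LogitSeparationError", "RankDeficientError"]


class LogitSeparationError(RuntimeError):
    """Logistic fit diverged, typically from (quasi-)complete separation."""


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; carries the offending column index."""

    def __init__(self, column: int, msg: str | None = None):
        self.column = column
        super().__init__(msg or f"design matrix is rank deficient at column {column}")


def _check_rank(X: np.ndarray) -> None:
    # QR with column pivoting would name the aliased column exactly; a cheap
    # proxy is the first diagonal of R that collapses.
    R = np.linalg.qr(X, mode="r")
    diag = np.abs(np.diag(R))
    tol = X.shape[0] * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = np.nonzero(diag <= tol)[0]
    if bad.size:
        raise RankDeficientError(int(bad[0]))


def ols_fit(X: np.ndarray, y: np.ndarray, check_rank: bool = False):
    """OLS via normal equations. Returns (beta, XtX_inv, sigma2_hat)."""
    if check_rank:
        _check_rank(X)
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        _check_rank(X)
        raise
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    dof = max(X.shape[0] - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    return beta, XtX_inv, sigma2


def logit_fit(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 60,
    check_rank: bool = False,
):
    """Logistic MLE via iteratively reweighted least squares.

    Returns (beta, cov) where cov is the inverse observed information.
    Raises LogitSeparationError when coefficients diverge (|eta| runaway),
    the standard symptom of separation.
    """
    if check_rank:
        _check_rank(X)
    n, p = X.shape
    beta = np.zeros(p)
    XtWX = None
    for _ in range(max_iter):
        eta = X @ beta
        if np.max(np.abs(eta)) > 40.0:
            raise LogitSeparationError(
                "logistic fit diverged (|linear predictor| > 40); "
                "data are likely separated"
            )
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        XtWX = Xw.T @ X
        try:
            beta_new = np.linalg.solve(XtWX, Xw.T @ z)
        except np.linalg.LinAlgError:
            _check_rank(X)
            raise
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    else:
        raise LogitSeparationError("logistic IRLS did not converge")
    cov = np.linalg.inv(XtWX)
    return beta, cov
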