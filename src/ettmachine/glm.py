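"""Lightweight IRLS fitters for main-terms linear and logistic models.

These are deliberately minimal Newton/IRLS solvers: the estimation loops
(bootstrap replicates, cross-validation folds, TMLE fluctuations) fit tens of
thousands of small GLMs, and offset support is required for the fluctuation
submodels.  Statsmodels is used as the independent cross-check in the test
suite, never as the hot path.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "expit",
    "logit",
    "fit_logistic",
    "fit_linear",
    "logistic_fluctuation",
    "SeparationWarning",
]

# probability floor used whenever a fitted probability feeds a logit/loss
PROB_EPS = 1e-9


class SeparationWarning(UserWarning):
    """Raised when a logistic fit appears separated and a ridge term is added."""


def expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    return np.log(p / (1.0 - p))


def _irls_logistic(X, y, offset, weights, ridge, max_iter, tol):
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta + offset
        mu = expit(eta)
        w = weights * np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta - offset + (y - mu) / np.clip(mu * (1.0 - mu), 1e-10, None)
        XtW = X.T * w
        A = XtW @ X
        if ridge > 0:
            A = A + ridge * np.eye(p)
        try:
            beta_new = np.linalg.solve(A, XtW @ z)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, XtW @ z, rcond=None)[0]
        if not np.all(np.isfinite(beta_new)):
            return beta, False
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol * (1.0 + np.max(np.abs(beta))):
            return beta, True
    return beta, False


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    *,
    offset: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    add_intercept: bool = True,
    ridge: float = 0.0,
    max_iter: int = 60,
    tol: float = 1e-11,
) -> np.ndarray:
    """Fit a binomial GLM by IRLS; returns the coefficient vector.

    If ``add_intercept`` the intercept is the first coefficient.  Apparent
    separation (non-convergence or exploding coefficients) triggers a ridge
    refit with a warning, mirroring the usual penalized fall-back.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n = len(y)
    if offset is None:
        offset = np.zeros(n)
    if weights is None:
        weights = np.ones(n)
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
    beta, converged = _irls_logistic(X, y, offset, weights, ridge, max_iter, tol)
    if (not converged) or np.max(np.abs(beta)) > 30.0:
        warnings.warn(
            "logistic fit did not converge cleanly (possible separation); "
            "refitting with a small ridge penalty",
            SeparationWarning,
            stacklevel=2,
        )
        beta, _ = _irls_logistic(X, y, offset, weights, max(ridge, 1e-3), max_iter, tol)
    return beta


def fit_linear(
    X: np.ndarray,
    y: np.ndarray,
    *,
    add_intercept: bool = True,
) -> np.ndarray:
    """Ordinary least squares via lstsq; intercept first when requested."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def logistic_fluctuation(
    y: np.ndarray,
    h: np.ndarray,
    offset: np.ndarray,
    *,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> float:
    """Scalar intercept-free logistic regression of ``y`` on the single
    covariate ``h`` with a fixed ``offset``; returns the coefficient.

    This is the fluctuation step of the targeting procedure: the offset is the
    logit of the current fit and ``h`` the clever covariate.  Solved by a
    guarded 1-d Newton iteration on the score equation sum(h * (y - mu)) = 0.
    """
    y = np.asarray(y, dtype=float)
    h = np.asarray(h, dtype=float)
    offset = np.asarray(offset, dtype=float)
    eps = 0.0
    for _ in range(max_iter):
        mu = expit(offset + eps * h)
        score = np.sum(h * (y - mu))
        info = np.sum(h * h * mu * (1.0 - mu))
        if info <= 1e-12:
            break
        step = score / info
        # damp enormous steps; keeps the iteration stable near separation
        step = np.clip(step, -5.0, 5.0)
        eps += step
        if abs(step) < tol:
            break
    return float(eps)
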