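"""Estimators of the effect of treatment among the treated (ETT).

The estimand is psi = E[ E(Y | S=1, C) - E(Y | S=0, C) | S=1 ]: the change in
mean outcome for the patients actually treated at large-volume centers had
they, covariates fixed, been treated at small-volume centers instead.

Four estimators are provided:

* unadjusted difference of group means;
* substitution (plug-in): psi-hat = mean over treated of Y_i - Qbar(0, C_i),
  with Qbar fit by main-terms regression or SuperLearner;
* TMLE: the substitution estimate after iterative dual fluctuation of the
  outcome fit and the propensity fit along their clever covariates, with an
  efficient-influence-curve standard error — doubly robust;
* propensity-score matching with replacement, allowing ties, and a caliper of
  0.05 SD of the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm, inference
from .cohort import SITE_COL, CohortTable
from .preprocess import DesignMatrix
from .superlearner import LearnerSpec, SLFit, fit_superlearner, sl_predict

__all__ = [
    "ETTEstimate",
    "OutcomeFit",
    "PropensityFit",
    "TMLEState",
    "MatchedSet",
    "unadjusted_difference",
    "fit_outcome_model",
    "fit_propensity",
    "substitution_ett",
    "tmle_ett",
    "matching_ett",
]

TMLE_PROB_FLOOR = 1e-3  # clipping for logits of bounded outcomes during targeting


@dataclass
class ETTEstimate:
    estimator: str
    psi: float
    se: float = float("nan")
    ci_lo: float = float("nan")
    ci_hi: float = float("nan")
    n_treated: int = 0
    n_discarded: int = 0

    def with_ci(self, se: float, level: float = 0.95) -> "ETTEstimate":
        lo, hi = inference.wald_ci(self.psi, se, level)
        return ETTEstimate(self.estimator, self.psi, se, lo, hi,
                           self.n_treated, self.n_discarded)


def _design_frame(design: DesignMatrix | pd.DataFrame) -> pd.DataFrame:
    return design.df if isinstance(design, DesignMatrix) else pd.DataFrame(design)


# ---------------------------------------------------------------------------
# unadjusted
# ---------------------------------------------------------------------------

def unadjusted_difference(cohort: CohortTable, outcome: str, level: float = 0.95) -> ETTEstimate:
    """Crude difference of mean outcomes, large minus small.

    Binary outcomes use the unpooled binomial variance, continuous the Welch
    two-sample variance; the interval is Wald."""
    mask = cohort.outcome_mask(outcome)
    y = cohort.outcome_values(outcome)[mask]
    s = cohort.site[mask]
    y1, y0 = y[s == 1], y[s == 0]
    if len(y1) == 0 or len(y0) == 0:
        raise ValueError("both site groups must be nonempty")
    psi = float(y1.mean() - y0.mean())
    if cohort.outcomes[outcome] == "binary":
        var = y1.mean() * (1 - y1.mean()) / len(y1) + y0.mean() * (1 - y0.mean()) / len(y0)
    else:
        var = y1.var(ddof=1) / len(y1) + y0.var(ddof=1) / len(y0)
    est = ETTEstimate("unadjusted", psi, n_treated=int((s == 1).sum()))
    return est.with_ci(float(np.sqrt(var)), level)


# ---------------------------------------------------------------------------
# nuisance fits
# ---------------------------------------------------------------------------

@dataclass
class OutcomeFit:
    """Conditional-mean fit Qbar(s, C), evaluable at either site value for
    every row by swapping the site column."""

    method: str  # regression | superlearner
    outcome_type: str  # binary | continuous
    columns: list[str]  # covariate design columns (site excluded)
    beta: np.ndarray | None = None
    slfit: SLFit | None = None
    y_bounds: tuple[float, float] | None = None  # continuous only: observed (min, max)
    site_interactions: list[str] | None = None  # regression: columns crossed with site

    def predict(self, design: DesignMatrix | pd.DataFrame, s: np.ndarray | int) -> np.ndarray:
        X = _design_frame(design)
        if list(X.columns) != self.columns:
            raise ValueError(
                f"design columns {list(X.columns)} do not match training columns {self.columns}"
            )
        s_col = np.broadcast_to(np.asarray(s, dtype=float), (len(X),))
        if self.method == "regression":
            M = self._model_matrix(X, s_col)
            eta = self.beta[0] + M @ self.beta[1:]
            return glm.expit(eta) if self.outcome_type == "binary" else eta
        frame = X.copy()
        frame.insert(0, SITE_COL, s_col)
        return sl_predict(self.slfit, frame)

    def _model_matrix(self, X: pd.DataFrame, s_col: np.ndarray) -> np.ndarray:
        cols = [s_col, X.to_numpy(dtype=float)]
        for name in self.site_interactions or []:
            cols.append((s_col * X[name].to_numpy(dtype=float))[:, None])
        return np.column_stack([c if np.ndim(c) > 1 else c[:, None] for c in cols])


def fit_outcome_model(
    design: DesignMatrix | pd.DataFrame,
    S: np.ndarray,
    y: np.ndarray,
    method: str = "superlearner",
    outcome_type: str = "binary",
    library: list[LearnerSpec] | None = None,
    K: int = 10,
    seed: int = 0,
    site_interactions: list[str] | None = None,
) -> OutcomeFit:
    """Fit Qbar(S, C) on the (site + design) matrix.

    ``method='regression'`` is a main-terms GLM (logistic for binary,
    ordinary linear for continuous); ``site_interactions`` optionally adds
    site-by-column product terms (e.g. to saturate a discrete design).
    ``method='superlearner'`` stacks the supplied library with the matching
    loss."""
    if method not in {"regression", "superlearner"}:
        raise ValueError(f"unknown outcome-model method {method!r}")
    X = _design_frame(design)
    S = np.asarray(S)
    y = np.asarray(y, dtype=float)
    bounds = None
    if outcome_type == "continuous":
        bounds = (float(np.min(y)), float(np.max(y)))
    fit = OutcomeFit(method=method, outcome_type=outcome_type,
                     columns=list(X.columns), y_bounds=bounds,
                     site_interactions=list(site_interactions or []) or None)
    M = fit._model_matrix(X, S.astype(float))
    if method == "regression":
        if outcome_type == "binary":
            fit.beta = glm.fit_logistic(M, y)
        else:
            fit.beta = glm.fit_linear(M, y)
    else:
        frame = X.copy()
        frame.insert(0, SITE_COL, S.astype(float))
        loss = "binomial" if outcome_type == "binary" else "squared"
        fit.slfit = fit_superlearner(frame, y, library=library, loss=loss, K=K, seed=seed)
    return fit


@dataclass
class PropensityFit:
    """Estimated P(S=1 | C), truncated into [delta, 1-delta]."""

    g: np.ndarray
    delta: float
    sigma_g: float
    columns: list[str]
    slfit: SLFit | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.delta < 0.5):
            raise ValueError("truncation delta must lie in [0, 0.5)")


def fit_propensity(
    design: DesignMatrix | pd.DataFrame,
    S: np.ndarray,
    method: str = "superlearner",
    library: list[LearnerSpec] | None = None,
    delta: float = 0.025,
    K: int = 10,
    seed: int = 0,
) -> PropensityFit:
    """Fit the propensity score on the covariate design (site excluded),
    truncate into [delta, 1-delta], and record the pooled SD of the truncated
    scores (used by the matching caliper)."""
    if not (0 <= delta < 0.5):
        raise ValueError("truncation delta must lie in [0, 0.5)")
    X = _design_frame(design)
    S = np.asarray(S, dtype=float)
    if len(np.unique(S)) < 2:
        raise ValueError("site indicator is constant; propensity undefined")
    if method == "superlearner":
        slfit = fit_superlearner(X, S, library=library, loss="binomial", K=K, seed=seed)
        raw = sl_predict(slfit, X)
    elif method == "regression":
        beta = glm.fit_logistic(X.to_numpy(dtype=float), S)
        raw = glm.expit(beta[0] + X.to_numpy(dtype=float) @ beta[1:])
        slfit = None
    elif method == "mean-only":
        raw = np.full(len(S), S.mean())
        slfit = None
    else:
        raise ValueError(f"unknown propensity method {method!r}")
    g = np.clip(raw, delta, 1 - delta)
    sigma = float(np.std(g, ddof=1)) if len(g) > 1 else 0.0
    return PropensityFit(g=g, delta=delta, sigma_g=sigma, columns=list(X.columns), slfit=slfit)


# ---------------------------------------------------------------------------
# substitution
# ---------------------------------------------------------------------------

def substitution_ett(
    design: DesignMatrix | pd.DataFrame,
    S: np.ndarray,
    y: np.ndarray,
    qfit: OutcomeFit,
    label: str | None = None,
) -> ETTEstimate:
    """Plug-in ETT: average over treated rows of Y_i - Qbar(0, C_i).

    No analytic standard error is attached; pair with the nonparametric
    bootstrap for inference."""
    S = np.asarray(S)
    y = np.asarray(y, dtype=float)
    treated = S == 1
    if not treated.any():
        raise ValueError("no treated (large-site) rows")
    q0 = qfit.predict(design, 0)
    psi = float(np.mean(y[treated] - q0[treated]))
    name = label or f"substitution-{'SL' if qfit.method == 'superlearner' else 'regression'}"
    return ETTEstimate(name, psi, n_treated=int(treated.sum()))


# ---------------------------------------------------------------------------
# TMLE
# ---------------------------------------------------------------------------

@dataclass
class TMLEState:
    """State of the iterative dual-fluctuation targeting procedure.

    For continuous outcomes all quantities live on the bounded [0, 1] scale;
    ``scale``/``offset`` map back to the raw outcome."""

    S: np.ndarray
    y: np.ndarray  # transformed scale
    Q1: np.ndarray
    Q0: np.ndarray
    g: np.ndarray
    p1: float
    delta: float
    psi: float  # transformed scale
    eps_q: float
    eps_g: float
    n_iter: int
    converged: bool
    outcome_type: str
    scale: float = 1.0
    offset: float = 0.0
    eps_history: list[tuple[float, float]] = field(default_factory=list)

    @property
    def QS(self) -> np.ndarray:
        return np.where(self.S == 1, self.Q1, self.Q0)

    @property
    def psi_raw(self) -> float:
        return self.psi * self.scale


def tmle_ett(
    design: DesignMatrix | pd.DataFrame,
    S: np.ndarray,
    y: np.ndarray,
    qfit: OutcomeFit,
    gfit: PropensityFit,
    tol: float = 1e-5,
    max_iter: int = 50,
    level: float = 0.95,
) -> tuple[ETTEstimate, TMLEState]:
    """Targeted update of the substitution estimator.

    Each cycle (i) fluctuates the outcome fit: intercept-free logistic
    regression of Y on the clever covariate H_Y(S, C) = 1{S=1} -
    1{S=0} g/(1-g) with offset logit Qbar(S, C); (ii) recomputes psi and
    fluctuates the propensity fit with clever covariate H_S(C) = Qbar(1,C) -
    Qbar(0,C) - psi and offset logit g.  The constant 1/P(S=1) factor of the
    canonical clever covariates is absorbed into the fluctuation coefficients
    (it does not change the submodel's span).  Iterates until both
    coefficients fall below ``tol`` in absolute value."""
    S = np.asarray(S).astype(int)
    y = np.asarray(y, dtype=float)
    treated = S == 1
    if not treated.any() or treated.all():
        raise ValueError("both site groups must be present")

    scale, off = 1.0, 0.0
    if qfit.outcome_type == "continuous":
        a, b = qfit.y_bounds
        if b <= a:
            raise ValueError("degenerate outcome range for the bounded transform")
        scale, off = b - a, a

    def to_unit(v):
        return np.clip((v - off) / scale, TMLE_PROB_FLOOR, 1 - TMLE_PROB_FLOOR)

    ystar = (y - off) / scale if qfit.outcome_type == "continuous" else y
    Q1 = to_unit(qfit.predict(design, 1) * 1.0) if qfit.outcome_type == "continuous" \
        else np.clip(qfit.predict(design, 1), TMLE_PROB_FLOOR, 1 - TMLE_PROB_FLOOR)
    Q0 = to_unit(qfit.predict(design, 0) * 1.0) if qfit.outcome_type == "continuous" \
        else np.clip(qfit.predict(design, 0), TMLE_PROB_FLOOR, 1 - TMLE_PROB_FLOOR)
    g = np.clip(gfit.g, gfit.delta, 1 - gfit.delta)
    p1 = float(np.mean(treated))

    eps_q = eps_g = np.inf
    history: list[tuple[float, float]] = []
    n_iter = 0
    psi = float(np.mean(Q1[treated] - Q0[treated]))
    while n_iter < max_iter and max(abs(eps_q), abs(eps_g)) >= tol:
        n_iter += 1
        # (i) outcome fluctuation
        h1 = np.ones(len(S))
        h0 = -g / (1 - g)
        h_obs = np.where(treated, h1, h0)
        eps_q = glm.logistic_fluctuation(ystar, h_obs, glm.logit(np.where(treated, Q1, Q0)))
        Q1 = glm.expit(glm.logit(Q1) + eps_q * h1)
        Q0 = glm.expit(glm.logit(Q0) + eps_q * h0)
        # (ii) propensity fluctuation
        psi = float(np.mean(Q1[treated] - Q0[treated]))
        h_s = Q1 - Q0 - psi
        eps_g = glm.logistic_fluctuation(S.astype(float), h_s, glm.logit(g))
        g = np.clip(glm.expit(glm.logit(g) + eps_g * h_s), gfit.delta, 1 - gfit.delta)
        history.append((eps_q, eps_g))

    converged = max(abs(eps_q), abs(eps_g)) < tol
    if not converged:
        warnings.warn(
            f"TMLE did not converge in {max_iter} iterations "
            f"(last |eps_Q|={abs(eps_q):.2e}, |eps_g|={abs(eps_g):.2e})",
            stacklevel=2,
        )
    at_bounds = np.mean((g <= gfit.delta + 1e-12) | (g >= 1 - gfit.delta - 1e-12))
    if at_bounds > 0.20:
        warnings.warn(
            f"propensity scores at the truncation bounds for {at_bounds:.0%} of rows; "
            "positivity is questionable", stacklevel=2,
        )

    psi = float(np.mean(Q1[treated] - Q0[treated]))
    state = TMLEState(
        S=S, y=ystar, Q1=Q1, Q0=Q0, g=g, p1=p1, delta=gfit.delta, psi=psi,
        eps_q=float(eps_q), eps_g=float(eps_g), n_iter=n_iter, converged=converged,
        outcome_type=qfit.outcome_type, scale=scale, offset=off, eps_history=history,
    )
    se = inference.tmle_eif_se(state) if converged else float("nan")
    est = ETTEstimate("tmle", state.psi_raw, n_treated=int(treated.sum()))
    if converged:
        est = est.with_ci(se, level)
    return est, state


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

@dataclass
class MatchedSet:
    treated_idx: np.ndarray  # matched treated row positions
    matches: list[np.ndarray]  # control row positions per matched treated row
    discarded_idx: np.ndarray  # treated rows with no control within the caliper
    caliper: float
    control_weight: dict[int, float]  # control row -> total reuse weight K_j

    @property
    def matched_rows(self) -> np.ndarray:
        """All rows (treated + used controls) participating in the matched set."""
        controls = sorted(self.control_weight)
        return np.concatenate([self.treated_idx, np.array(controls, dtype=int)])


def matching_ett(
    S: np.ndarray,
    y: np.ndarray,
    gfit: PropensityFit,
    caliper_sd: float = 0.05,
    level: float = 0.95,
) -> tuple[ETTEstimate, MatchedSet]:
    """Nearest-neighbor propensity matching of each treated row to controls,
    with replacement and allowing ties.

    Ties at the exactly minimal score distance are all kept and their
    outcomes averaged.  Treated rows with no control within ``caliper_sd``
    standard deviations of the score are discarded and counted.  The standard
    error is the reuse-weighted paired variance of
    :func:`ettmachine.inference.matching_se`."""
    S = np.asarray(S).astype(int)
    y = np.asarray(y, dtype=float)
    g = gfit.g
    t_idx = np.flatnonzero(S == 1)
    c_idx = np.flatnonzero(S == 0)
    if len(t_idx) == 0 or len(c_idx) == 0:
        raise ValueError("both site groups must be present")
    caliper = caliper_sd * gfit.sigma_g

    dist = np.abs(g[t_idx][:, None] - g[c_idx][None, :])
    dmin = dist.min(axis=1)
    keep = dmin <= caliper
    if not keep.any():
        raise ValueError("every treated row fell outside the caliper")

    matches: list[np.ndarray] = []
    diffs = []
    weight: dict[int, float] = {}
    for row, ok in enumerate(keep):
        if not ok:
            continue
        tied = c_idx[dist[row] == dmin[row]]
        matches.append(tied)
        diffs.append(y[t_idx[row]] - y[tied].mean())
        for j in tied:
            weight[int(j)] = weight.get(int(j), 0.0) + 1.0 / len(tied)

    matched = MatchedSet(
        treated_idx=t_idx[keep], matches=matches, discarded_idx=t_idx[~keep],
        caliper=caliper, control_weight=weight,
    )
    psi = float(np.mean(diffs))
    est = ETTEstimate("matching", psi, n_treated=int(len(t_idx)),
                      n_discarded=int((~keep).sum()))
    if len(diffs) >= 2:
        se = inference.matching_se(matched, y, g)
        est = est.with_ci(se, level)
        est.n_discarded = int((~keep).sum())
    return est, matched
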