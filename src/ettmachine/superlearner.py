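"""Cross-validated ensemble stacking (SuperLearner).

The stacking machinery — V-fold cross-validated predictions for a library of
learners, the convex weight vector minimizing cross-validated risk, and the
full-data refit — is implemented here.  Individual library members delegate to
scikit-learn where an established estimator exists (penalized GLM, tree
ensemble, nearest neighbors); the mean-only and main-terms GLM learners use
the package's own fitters.

The ensemble's cross-validated risk is never worse than the best single
learner's: the simplex contains every vertex, and the solver falls back to the
best vertex whenever numerical optimization fails to beat it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import glm

__all__ = [
    "Folds",
    "LearnerSpec",
    "SLFit",
    "make_folds",
    "fit_superlearner",
    "sl_predict",
    "default_library",
    "glm_only_library",
]

DEFAULT_BOUND = 1e-3
VALID_FAMILIES = {
    "mean-only",
    "glm",
    "penalized-glm",
    "tree-ensemble",
    "knn",
}


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass
class Folds:
    K: int
    assignment: np.ndarray  # per-row fold index in [0, K)

    def __post_init__(self) -> None:
        counts = np.bincount(self.assignment, minlength=self.K)
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes differ by more than 1")


def make_folds(
    n: int, K: int = 10, seed: int = 0, stratify_on: np.ndarray | None = None
) -> Folds:
    """Random fold assignment with sizes differing by at most one.

    With ``stratify_on`` (a binary vector) the positives are dealt round-robin
    across folds, so each fold's positive count differs from proportionality
    by at most one — this is what keeps rare-outcome folds from being empty of
    events.
    """
    if not 2 <= K <= n:
        raise ValueError(f"need 2 <= K <= n, got K={K}, n={n}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratify_on is None:
        order = rng.permutation(n)
        assignment[order] = np.arange(n) % K
    else:
        # deal positives round-robin, then keep the counter running through the
        # negatives: positives per fold AND total fold sizes differ by <= 1
        stratify_on = np.asarray(stratify_on)
        fold_order = rng.permutation(K)
        counter = 0
        for level in (1, 0):
            idx = np.flatnonzero(stratify_on == level)
            idx = idx[rng.permutation(len(idx))]
            assignment[idx] = fold_order[(counter + np.arange(len(idx))) % K]
            counter += len(idx)
    return Folds(K=K, assignment=assignment)


# ---------------------------------------------------------------------------
# learners
# ---------------------------------------------------------------------------

@dataclass
class LearnerSpec:
    name: str
    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in VALID_FAMILIES:
            raise ValueError(
                f"unknown learner family {self.family!r}; valid: {sorted(VALID_FAMILIES)}"
            )


class _MeanLearner:
    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


class _GLMLearner:
    def __init__(self, binary: bool):
        self.binary = binary

    def fit(self, X, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", glm.SeparationWarning)
            if self.binary:
                self.beta_ = glm.fit_logistic(X, y)
            else:
                self.beta_ = glm.fit_linear(X, y)
        return self

    def predict(self, X):
        eta = self.beta_[0] + np.asarray(X, dtype=float) @ self.beta_[1:]
        return glm.expit(eta) if self.binary else eta


def _build_learner(spec: LearnerSpec, binary: bool):
    hp = dict(spec.hyperparameters)
    if spec.family == "mean-only":
        return _MeanLearner()
    if spec.family == "glm":
        return _GLMLearner(binary)
    if spec.family == "penalized-glm":
        if binary:
            from sklearn.linear_model import LogisticRegressionCV

            return _ProbWrapper(LogisticRegressionCV(
                Cs=hp.get("Cs", 5), cv=hp.get("cv", 3), penalty="l1",
                solver="liblinear", max_iter=200))
        from sklearn.linear_model import LassoCV

        return LassoCV(cv=hp.get("cv", 3), n_alphas=hp.get("n_alphas", 20))
    if spec.family == "tree-ensemble":
        kwargs = dict(n_estimators=hp.get("n_estimators", 100),
                      max_depth=hp.get("max_depth", 2),
                      learning_rate=hp.get("learning_rate", 0.1),
                      random_state=hp.get("random_state", 0))
        if binary:
            from sklearn.ensemble import GradientBoostingClassifier

            return _ProbWrapper(GradientBoostingClassifier(**kwargs))
        from sklearn.ensemble import GradientBoostingRegressor

        return GradientBoostingRegressor(**kwargs)
    if spec.family == "knn":
        k = hp.get("n_neighbors", 20)
        if binary:
            from sklearn.neighbors import KNeighborsClassifier

            return _ProbWrapper(KNeighborsClassifier(n_neighbors=k))
        from sklearn.neighbors import KNeighborsRegressor

        return KNeighborsRegressor(n_neighbors=k)
    raise ValueError(spec.family)  # pragma: no cover


class _ProbWrapper:
    """Adapts a sklearn classifier to the predict-a-probability interface,
    including the single-class degenerate case."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        y = np.asarray(y)
        self.constant_ = float(y[0]) if len(np.unique(y)) == 1 else None
        if self.constant_ is None:
            self.estimator.fit(X, y.astype(int))
        return self

    def predict(self, X):
        if self.constant_ is not None:
            return np.full(len(X), self.constant_)
        proba = self.estimator.predict_proba(X)
        return proba[:, list(self.estimator.classes_).index(1)]


def default_library() -> list[LearnerSpec]:
    """Default five-member library, ordered simplest first (the tie-break
    order for degenerate weight solutions)."""
    return [
        LearnerSpec("mean", "mean-only"),
        LearnerSpec("glm", "glm"),
        LearnerSpec("lasso", "penalized-glm"),
        LearnerSpec("gbm", "tree-ensemble"),
        LearnerSpec("knn20", "knn"),
    ]


def glm_only_library() -> list[LearnerSpec]:
    """Reduced two-member library (mean-only + main-terms GLM) used in
    replicate studies where speed matters."""
    return [LearnerSpec("mean", "mean-only"), LearnerSpec("glm", "glm")]


# ---------------------------------------------------------------------------
# stacking
# ---------------------------------------------------------------------------

@dataclass
class SLFit:
    library: list[LearnerSpec]
    columns: list[str]
    loss: str  # squared | binomial
    bound: float
    cv_predictions: np.ndarray  # n x L
    cv_risks: np.ndarray  # per learner (inf where the learner failed)
    weights: np.ndarray  # simplex vector, zero on failed learners
    ensemble_cv_risk: float
    full_fits: list  # fitted learner objects (None where failed)

    def risk_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "learner": [s.name for s in self.library],
            "cv_risk": self.cv_risks,
            "weight": self.weights,
        })


def _risk(y: np.ndarray, pred: np.ndarray, loss: str, bound: float) -> float:
    if loss == "binomial":
        p = np.clip(pred, bound, 1 - bound)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return float(np.mean((y - pred) ** 2))


def _solve_weights(
    Z: np.ndarray, y: np.ndarray, loss: str, bound: float, ok: np.ndarray
) -> np.ndarray:
    """Convex weights minimizing CV risk over the simplex, restricted to the
    learners that did not fail."""
    L = Z.shape[1]
    idx = np.flatnonzero(ok)
    Zok = Z[:, idx]
    m = len(idx)
    if m == 1:
        alpha_ok = np.ones(1)
    elif loss == "squared":
        coef, _ = optimize.nnls(Zok, y)
        alpha_ok = coef / coef.sum() if coef.sum() > 0 else np.full(m, 1.0 / m)
    else:
        def nll(a):
            return _risk(y, Zok @ a, "binomial", bound)

        res = optimize.minimize(
            nll, np.full(m, 1.0 / m), method="SLSQP",
            bounds=[(0.0, 1.0)] * m,
            constraints=[{"type": "eq", "fun": lambda a: a.sum() - 1.0}],
            options={"maxiter": 200, "ftol": 1e-10},
        )
        alpha_ok = np.clip(res.x, 0, None)
        alpha_ok = alpha_ok / alpha_ok.sum()
    # the simplex contains every vertex: never do worse than the best single
    # learner (ties broken toward the simpler, earlier learner)
    achieved = _risk(y, Zok @ alpha_ok, loss, bound)
    vertex_risks = [_risk(y, Zok[:, j], loss, bound) for j in range(m)]
    best = int(np.argmin(vertex_risks))
    if vertex_risks[best] < achieved - 1e-12:
        alpha_ok = np.zeros(m)
        alpha_ok[best] = 1.0
    alpha = np.zeros(L)
    alpha[idx] = alpha_ok
    return alpha


def fit_superlearner(
    X: pd.DataFrame,
    y: np.ndarray,
    library: list[LearnerSpec] | None = None,
    folds: Folds | None = None,
    loss: str = "binomial",
    K: int = 10,
    seed: int = 0,
    bound: float = DEFAULT_BOUND,
) -> SLFit:
    """Fit the stacked ensemble.

    Rare binary outcomes (prevalence below 5%) get outcome-stratified folds
    unless explicit ``folds`` are supplied.  A learner that raises on any
    training split receives infinite CV risk and zero weight (with a warning)
    rather than failing the whole fit.
    """
    if library is None:
        library = default_library()
    if not library:
        raise ValueError("learner library is empty")
    if loss not in {"binomial", "squared"}:
        raise ValueError(f"unknown loss {loss!r}")
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("y contains missing values; drop those rows first")
    if loss == "binomial" and not set(np.unique(y)).issubset({0.0, 1.0}):
        raise ValueError("binomial loss requires y in {0, 1}")
    n = len(y)
    if folds is None:
        stratify = None
        if loss == "binomial" and 0 < np.mean(y) < 0.05:
            stratify = y
        folds = make_folds(n, K=min(K, n), seed=seed, stratify_on=stratify)

    Xv = X.to_numpy(dtype=float)
    L = len(library)
    Z = np.full((n, L), np.nan)
    ok = np.ones(L, dtype=bool)
    binary = loss == "binomial"
    for k in range(folds.K):
        val = folds.assignment == k
        train = ~val
        for j, spec in enumerate(library):
            if not ok[j]:
                continue
            try:
                learner = _build_learner(spec, binary).fit(Xv[train], y[train])
                Z[val, j] = learner.predict(Xv[val])
            except Exception as exc:  # robustness contract: drop the learner
                warnings.warn(
                    f"learner {spec.name!r} failed on fold {k}: {exc!r}; "
                    "assigned infinite CV risk", stacklevel=2,
                )
                ok[j] = False
    if binary:
        Z[:, ok] = np.clip(Z[:, ok], bound, 1 - bound)
    if not ok.any():
        raise RuntimeError("every learner in the library failed")

    cv_risks = np.array([
        _risk(y, Z[:, j], loss, bound) if ok[j] else np.inf for j in range(L)
    ])
    weights = _solve_weights(np.nan_to_num(Z), y, loss, bound, ok)
    ensemble_risk = _risk(y, np.nan_to_num(Z) @ weights, loss, bound)

    full_fits: list = []
    for j, spec in enumerate(library):
        if not ok[j]:
            full_fits.append(None)
            continue
        try:
            full_fits.append(_build_learner(spec, binary).fit(Xv, y))
        except Exception as exc:
            warnings.warn(
                f"learner {spec.name!r} failed on the full data: {exc!r}",
                stacklevel=2,
            )
            full_fits.append(None)
            weights[j] = 0.0
            if weights.sum() == 0:
                raise
            weights = weights / weights.sum()

    return SLFit(
        library=list(library), columns=list(X.columns), loss=loss, bound=bound,
        cv_predictions=Z, cv_risks=cv_risks, weights=weights,
        ensemble_cv_risk=ensemble_risk, full_fits=full_fits,
    )


def sl_predict(fit: SLFit, X_new: pd.DataFrame) -> np.ndarray:
    """Ensemble prediction: the weight-averaged full-data refit predictions,
    clipped into the probability bounds for binomial loss."""
    X_new = pd.DataFrame(X_new)
    if list(X_new.columns) != fit.columns:
        missing = set(fit.columns) - set(X_new.columns)
        extra = set(X_new.columns) - set(fit.columns)
        raise ValueError(
            f"column mismatch with training design: missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}, order must match {fit.columns}"
        )
    Xv = X_new.to_numpy(dtype=float)
    pred = np.zeros(len(X_new))
    for w, learner in zip(fit.weights, fit.full_fits):
        if w > 0 and learner is not None:
            pred += w * np.asarray(learner.predict(Xv), dtype=float)
    if fit.loss == "binomial":
        pred = np.clip(pred, fit.bound, 1 - fit.bound)
    return pred
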