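"""Replicate studies over the synthetic mechanism.

Each function draws repeated cohorts from a known data-generating mechanism,
runs part of the estimation machinery, and summarizes operating
characteristics (bias, confidence-interval coverage, type-I error, balance
improvement).  They back both the validation suite and the reporting
scripts; replicate counts and sample sizes default to the study sizes used
throughout the package's own evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SITE_COL
from .config import GeneratorConfig
from .diagnostics import matched_balance
from .estimators import (
    fit_outcome_model,
    fit_propensity,
    matching_ett,
    substitution_ett,
    tmle_ett,
    unadjusted_difference,
)
from .inference import bootstrap_ci
from .preprocess import expand_missingness
from .simulate import default_config, generate_cohort, null_config, true_ett
from .superlearner import LearnerSpec, glm_only_library

MEAN_ONLY = [LearnerSpec("mean", "mean-only")]


def _prepared(cfg: GeneratorConfig, seed: int, outcome: str):
    coh = generate_cohort(cfg, seed=seed)
    design = expand_missingness(coh)
    return coh, design, coh.outcome_values(outcome), coh.site


@dataclass
class RecoveryResult:
    psi0: float
    estimates: np.ndarray
    coverage: float
    n_reps: int

    @property
    def bias(self) -> float:
        return float(self.estimates.mean() - self.psi0)

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of the mean estimate."""
        return float(self.estimates.std(ddof=1) / np.sqrt(self.n_reps))


def tmle_recovery_study(
    n_reps: int = 200,
    n_patients: int = 1250,
    outcome: str = "overall_mortality",
    seed: int = 0,
    config: GeneratorConfig | None = None,
    n_mc_truth: int = 1_000_000,
) -> RecoveryResult:
    """Repeated-cohort bias and EIF-Wald coverage of TMLE with the reduced
    (mean + main-terms GLM) stacking library under the default mechanism."""
    cfg = config or default_config(n_patients=n_patients)
    truth = true_ett(cfg, outcome, n_mc=n_mc_truth, seed=seed + 11)
    psis, hits = [], 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_reps):
            _, d, y, S = _prepared(cfg, seed + r, outcome)
            q = fit_outcome_model(d.df, S, y, method="superlearner",
                                  library=glm_only_library(), seed=r)
            g = fit_propensity(d.df, S, method="superlearner",
                               library=glm_only_library(), seed=r)
            est, _ = tmle_ett(d.df, S, y, q, g)
            psis.append(est.psi)
            hits += est.ci_lo <= truth.ett <= est.ci_hi
    return RecoveryResult(psi0=truth.ett, estimates=np.array(psis),
                          coverage=hits / n_reps, n_reps=n_reps)


def double_robustness_study(
    n_reps: int = 100,
    n_patients: int = 2000,
    outcome: str = "overall_mortality",
    seed: int = 0,
) -> dict[str, RecoveryResult]:
    """Two deliberate misspecifications of the nuisance fits.

    Scenario ``q_wrong``: mean-only outcome fit with a correctly specified
    propensity — TMLE must stay unbiased, the plain substitution estimator
    must not.  Scenario ``g_wrong``: correct outcome fit with a constant
    propensity — TMLE must stay unbiased, matching (which then pairs at
    random) must not."""
    cfg = default_config(n_patients=n_patients)
    truth = true_ett(cfg, outcome, n_mc=500_000, seed=seed + 7)
    bags: dict[str, list[float]] = {k: [] for k in
                                    ("tmle_q_wrong", "subs_q_wrong",
                                     "tmle_g_wrong", "match_g_wrong")}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_reps):
            _, d, y, S = _prepared(cfg, seed + 4000 + r, outcome)
            q_bad = fit_outcome_model(d.df, S, y, method="superlearner",
                                      library=MEAN_ONLY, K=5, seed=r)
            g_ok = fit_propensity(d.df, S, method="regression")
            bags["tmle_q_wrong"].append(tmle_ett(d.df, S, y, q_bad, g_ok)[0].psi)
            bags["subs_q_wrong"].append(substitution_ett(d.df, S, y, q_bad).psi)
            q_ok = fit_outcome_model(d.df, S, y, method="regression")
            g_bad = fit_propensity(d.df, S, method="mean-only")
            bags["tmle_g_wrong"].append(tmle_ett(d.df, S, y, q_ok, g_bad)[0].psi)
            bags["match_g_wrong"].append(matching_ett(S, y, g_bad)[0].psi)
    return {k: RecoveryResult(psi0=truth.ett, estimates=np.array(v),
                              coverage=float("nan"), n_reps=n_reps)
            for k, v in bags.items()}


def null_calibration_study(
    n_reps: int = 200,
    n_patients: int = 1250,
    outcome: str = "overall_mortality",
    B: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Fraction of nominal-95% intervals excluding zero under the no-effect,
    randomized-site mechanism, for the unadjusted difference, the regression
    substitution estimator with bootstrap intervals, and TMLE."""
    cfg = null_config(n_patients=n_patients)
    rej = {"unadjusted": 0, "substitution_bootstrap": 0, "tmle": 0}

    def sub_estimator(frame: pd.DataFrame) -> float:
        Sb = frame[SITE_COL].to_numpy(dtype=int)
        yb = frame["__y__"].to_numpy(dtype=float)
        Xb = frame.drop(columns=[SITE_COL, "__y__"])
        qb = fit_outcome_model(Xb, Sb, yb, method="regression")
        return substitution_ett(Xb, Sb, yb, qb).psi

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_reps):
            coh, d, y, S = _prepared(cfg, seed + r, outcome)
            un = unadjusted_difference(coh, outcome)
            rej["unadjusted"] += not (un.ci_lo <= 0 <= un.ci_hi)
            q = fit_outcome_model(d.df, S, y, method="superlearner",
                                  library=glm_only_library(), seed=r)
            g = fit_propensity(d.df, S, method="superlearner",
                               library=glm_only_library(), seed=r)
            tm, _ = tmle_ett(d.df, S, y, q, g)
            rej["tmle"] += not (tm.ci_lo <= 0 <= tm.ci_hi)
            frame = d.df.copy()
            frame[SITE_COL] = S
            frame["__y__"] = y
            boot = bootstrap_ci(sub_estimator, frame, B=B, seed=seed + r)
            rej["substitution_bootstrap"] += not (boot.ci_lo <= 0 <= boot.ci_hi)
    return {k: v / n_reps for k, v in rej.items()}


def balance_improvement_study(
    n_reps: int = 50, n_patients: int = 800, seed: int = 0
) -> float:
    """Fraction of replicates of the confounded default mechanism in which
    caliper matching reduces the mean absolute standardized mean difference."""
    cfg = default_config(n_patients=n_patients)
    improved = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for r in range(n_reps):
            coh, d, y, S = _prepared(cfg, seed + 600 + r, "overall_mortality")
            gfit = fit_propensity(d.df, S, method="regression")
            _, matched = matching_ett(S, y, gfit)
            report = matched_balance(matched, d, S)
            improved += (report.smd["smd_post"].abs().mean()
                         < report.smd["smd_pre"].abs().mean())
    return improved / n_reps


# ---------------------------------------------------------------------------
# diagnostics scenario mechanisms (the three schematic regimes)
# ---------------------------------------------------------------------------

@dataclass
class _TrueMeanFit:
    """Oracle conditional-mean function posing as an OutcomeFit: the perfect
    predictor under which counterfactual residuals isolate the true
    patient-level effect profile plus noise."""

    fn: callable  # (x_array, s) -> mean
    columns: tuple = ("x",)
    method: str = "oracle"
    outcome_type: str = "continuous"

    def predict(self, design, s):
        x = np.asarray(pd.DataFrame(design)["x"], dtype=float)
        return self.fn(x, s)


def diagnostics_scenario(
    regime: str, n: int = 5000, seed: int = 0, effect: float = -0.15,
    cutoff: float = 0.6, noise_sd: float = 0.25,
):
    """Generate one of the three schematic residual-curve regimes on a
    uniform risk axis: ``null`` (no site effect), ``uniform`` (constant
    site effect), ``step`` (effect only above a risk cutoff).

    Returns (ResidualSet, true mean function) where residuals were computed
    against the oracle fit, so the smoothed curves estimate the effect
    profile itself."""
    from .diagnostics import ResidualSet

    rng = np.random.default_rng(seed)
    x = rng.random(n)
    s = (rng.random(n) < 0.5).astype(int)
    baseline = 0.1 + 0.6 * x

    if regime == "null":
        eff = np.zeros(n)
    elif regime == "uniform":
        eff = np.full(n, effect)
    elif regime == "step":
        eff = np.where(x >= cutoff, effect, 0.0)
    else:
        raise ValueError(f"unknown regime {regime!r}")

    y = baseline + s * eff + noise_sd * rng.normal(size=n)

    def true_mean(xv, sv):
        sv = np.broadcast_to(np.asarray(sv, dtype=float), np.shape(xv))
        if regime == "null":
            e = 0.0
        elif regime == "uniform":
            e = effect
        else:
            e = np.where(np.asarray(xv) >= cutoff, effect, 0.0)
        return 0.1 + 0.6 * np.asarray(xv) + sv * e

    fit = _TrueMeanFit(fn=true_mean)
    resid = y - fit.predict(pd.DataFrame({"x": x}), 1 - s)
    return ResidualSet(outcome="scenario_" + regime, ids=np.arange(n), site=s,
                       residual=resid, risk=x), fit
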