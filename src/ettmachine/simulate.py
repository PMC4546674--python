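"""Synthetic trauma-cohort generator with a known causal mechanism.

Emulates the statistical structure of a multi-center transfusion cohort:
~1,242 patients split roughly 44/56 between large- and small-volume centers,
site assignment confounded by demographics and emergency-department labs,
covariate missingness whose rate depends on site and severity, binary
outcomes from rare (multiple organ failure, ~1.4%) to common (overall
mortality, ~21%), a non-negative continuous transfusion-volume outcome, and a
site effect modified by injury type so the effect among the treated (ETT)
differs from the average effect (ATE).

Because the mechanism is known, the true ETT is computable by Monte Carlo
(:func:`true_ett`), giving every downstream estimator a verifiable target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ID_COL, SITE_COL, CohortTable
from .config import (
    ConfigurationError,
    CovariateSpec,
    GeneratorConfig,
    MissingnessModel,
    OutcomeModel,
    SiteModel,
)
from .glm import expit

__all__ = [
    "default_config",
    "null_config",
    "generate_cohort",
    "true_ett",
    "TruthReport",
    "make_discrete_toy",
    "DiscreteToy",
]

# Named substreams: toggling one component (e.g. missingness) must not perturb
# the draws of any other component under the same master seed.
_STREAMS = {"covariates": 0, "site": 1, "missingness": 2, "outcomes": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],)))


# ---------------------------------------------------------------------------
# default mechanisms
# ---------------------------------------------------------------------------

def default_config(n_patients: int = 1242, seed: int = 0) -> GeneratorConfig:
    """The default emulator mechanism.

    Covariate marginals and the directions of the site/outcome coefficients
    follow the qualitative picture of a large observational trauma
    transfusion cohort (large centers treat younger patients with more
    penetrating injury and higher ED hemoglobin; base deficit and hemoglobin
    are missing at site-dependent rates).  The mortality model carries a
    protective site main effect plus a site-by-penetrating interaction, so
    the ETT differs from the ATE.  Coefficients are on standardized
    covariates; intercepts were calibrated once against the targeted marginal
    rates and are frozen here.
    """
    covariates = [
        CovariateSpec("age", "truncated_normal", {"mean": 41.0, "sd": 18.5, "lower": 16.0, "upper": 90.0}),
        CovariateSpec("male", "bernoulli", {"p": 0.74}, kind="binary"),
        CovariateSpec("penetrating", "bernoulli", {"p": 0.35}, kind="binary"),
        CovariateSpec("iss", "truncated_gamma", {"mean": 26.0, "sd": 15.0, "lower": 1.0, "upper": 75.0}),
        CovariateSpec("ed_sbp", "normal", {"mean": 108.0, "sd": 31.0}),
        CovariateSpec("hemoglobin", "normal", {"mean": 11.7, "sd": 2.3}),
        CovariateSpec("base_deficit", "normal", {"mean": -7.0, "sd": 5.6}),
    ]
    site_model = SiteModel(
        intercept=-0.279,
        coefficients={
            "age": -1.10,
            "penetrating": 0.45,
            "hemoglobin": 0.60,
        },
    )
    missingness = [
        MissingnessModel("hemoglobin", intercept=-3.68, site_coefficient=0.78),
        MissingnessModel(
            "base_deficit",
            intercept=-0.98,
            site_coefficient=-0.55,
            coefficients={"iss": 0.30},
        ),
        MissingnessModel("ed_sbp", intercept=-3.74, site_coefficient=0.17),
    ]
    outcomes = [
        OutcomeModel(
            "overall_mortality",
            family="bernoulli-logit",
            intercept=-1.595,
            coefficients={
                "age": 0.55,
                "iss": 0.80,
                "ed_sbp": -0.45,
                "base_deficit": -0.50,
                "hemoglobin": -0.20,
                "penetrating": 0.20,
                "male": 0.05,
            },
            site_coefficient=-0.30,
            interactions={"penetrating": -0.45},
        ),
        OutcomeModel(
            "mof",
            family="bernoulli-logit",
            intercept=-4.342,
            coefficients={"iss": 0.55, "base_deficit": -0.30},
            site_coefficient=-0.25,
        ),
        OutcomeModel(
            "plasma_units",
            family="gamma-loglinear",
            intercept=1.55,
            coefficients={"iss": 0.30, "ed_sbp": -0.15, "hemoglobin": -0.10},
            site_coefficient=0.45,
            shape=0.8,
        ),
    ]
    return GeneratorConfig(
        n_patients=n_patients,
        covariates=covariates,
        site_model=site_model,
        missingness=missingness,
        outcomes=outcomes,
        seed=seed,
    )


def null_config(n_patients: int = 1242, seed: int = 0, randomized: bool = True) -> GeneratorConfig:
    """No-effect mechanism: all site coefficients in every outcome model are
    zero.  With ``randomized`` (default) the site model is intercept-only as
    well, so even the crude difference is unbiased for the null — the setting
    in which type-I error of all estimators is interpretable."""
    cfg = default_config(n_patients=n_patients, seed=seed)
    for om in cfg.outcomes:
        om.site_coefficient = 0.0
        om.interactions = {}
    if randomized:
        cfg.site_model = SiteModel(intercept=-0.226, coefficients={})
    return cfg


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _draw_covariates(config: GeneratorConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for spec in config.covariates:
        p = spec.params
        if spec.distribution == "normal":
            x = rng.normal(p["mean"], p["sd"], size=n)
        elif spec.distribution == "truncated_normal":
            a = (p["lower"] - p["mean"]) / p["sd"]
            b = (p["upper"] - p["mean"]) / p["sd"]
            x = stats.truncnorm.ppf(rng.random(n), a, b, loc=p["mean"], scale=p["sd"])
        elif spec.distribution == "truncated_gamma":
            k = (p["mean"] / p["sd"]) ** 2
            theta = p["sd"] ** 2 / p["mean"]
            lo = stats.gamma.cdf(p["lower"], k, scale=theta)
            hi = stats.gamma.cdf(p["upper"], k, scale=theta)
            x = stats.gamma.ppf(lo + rng.random(n) * (hi - lo), k, scale=theta)
        elif spec.distribution == "bernoulli":
            x = (rng.random(n) < p["p"]).astype(float)
        else:  # pragma: no cover - guarded by CovariateSpec validation
            raise ConfigurationError(f"unknown distribution {spec.distribution!r}")
        cols[spec.name] = x
    return pd.DataFrame(cols)


def _standardized(config: GeneratorConfig, C: pd.DataFrame, name: str) -> np.ndarray:
    spec = config.covariate(name)
    return (C[name].to_numpy() - spec.center) / spec.scale


def _site_logit(config: GeneratorConfig, C: pd.DataFrame) -> np.ndarray:
    lp = np.full(len(C), config.site_model.intercept)
    for name, coef in config.site_model.coefficients.items():
        lp += coef * _standardized(config, C, name)
    return lp


def outcome_linear_predictor(
    config: GeneratorConfig, model: OutcomeModel, C: pd.DataFrame, s: np.ndarray | int
) -> np.ndarray:
    """Linear predictor of one outcome model at site value ``s`` (scalar or
    per-row), evaluated on complete (pre-masking) covariates."""
    s = np.broadcast_to(np.asarray(s, dtype=float), (len(C),))
    lp = np.full(len(C), model.intercept)
    for name, coef in model.coefficients.items():
        lp += coef * _standardized(config, C, name)
    lp += model.site_coefficient * s
    for name, coef in model.interactions.items():
        lp += coef * s * _standardized(config, C, name)
    return lp


def conditional_mean(
    config: GeneratorConfig, model: OutcomeModel, C: pd.DataFrame, s: np.ndarray | int
) -> np.ndarray:
    """True E[Y | S=s, C] under the mechanism."""
    lp = outcome_linear_predictor(config, model, C, s)
    if model.family == "bernoulli-logit":
        return expit(lp)
    if model.family == "gamma-loglinear":
        return np.exp(lp)
    if model.family == "normal-identity":
        return lp
    # lognormal-loglinear: log Y ~ Normal(lp, shape^2)
    return np.exp(lp + 0.5 * model.shape**2)


def _draw_outcome(
    model: OutcomeModel, mean_or_lp: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if model.family == "bernoulli-logit":
        return (rng.random(len(mean_or_lp)) < expit(mean_or_lp)).astype(float)
    if model.family == "gamma-loglinear":
        mu = np.exp(mean_or_lp)
        return rng.gamma(model.shape, mu / model.shape)
    if model.family == "normal-identity":
        return rng.normal(mean_or_lp, model.shape)
    return np.exp(rng.normal(mean_or_lp, model.shape))


def generate_cohort(config: GeneratorConfig, seed: int | None = None) -> CohortTable:
    """Draw one cohort from the mechanism.

    Outcomes are generated from the complete (pre-masking) covariates;
    missingness then masks covariate values only.  Identical (config, seed)
    pairs yield identical tables.
    """
    seed = config.seed if seed is None else seed
    n = config.n_patients
    C = _draw_covariates(config, n, _rng(seed, "covariates"))
    site = (_rng(seed, "site").random(n) < expit(_site_logit(config, C))).astype(int)

    out_rng = _rng(seed, "outcomes")
    outcome_cols = {}
    outcome_types = {}
    for model in config.outcomes:
        lp = outcome_linear_predictor(config, model, C, site)
        outcome_cols[model.name] = _draw_outcome(model, lp, out_rng)
        outcome_types[model.name] = model.outcome_type

    miss_rng = _rng(seed, "missingness")
    masked = C.copy()
    for mm in config.missingness:
        lp = np.full(n, mm.intercept) + mm.site_coefficient * site
        for name, coef in mm.coefficients.items():
            lp += coef * _standardized(config, C, name)
        if mm.self_coefficient:
            lp += mm.self_coefficient * _standardized(config, C, mm.covariate)
        drop = miss_rng.random(n) < expit(lp)
        masked.loc[drop, mm.covariate] = np.nan

    df = pd.concat(
        [
            pd.DataFrame({ID_COL: np.arange(n), SITE_COL: site}),
            pd.DataFrame(outcome_cols),
            masked,
        ],
        axis=1,
    )
    covariate_types = {spec.name: spec.kind for spec in config.covariates}
    return CohortTable(df, outcomes=outcome_types, covariates=covariate_types)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class TruthReport:
    outcome: str
    ett: float
    ett_mc_se: float
    ate: float
    ate_mc_se: float
    n_mc: int

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "ett": self.ett,
            "ett_mc_se": self.ett_mc_se,
            "ate": self.ate,
            "ate_mc_se": self.ate_mc_se,
            "n_mc": self.n_mc,
        }


def true_ett(
    config: GeneratorConfig, outcome: str, n_mc: int = 1_000_000, seed: int = 0
) -> TruthReport:
    """True ETT and ATE of the mechanism by Monte Carlo.

    Draws ``n_mc`` covariate vectors and site labels; the ETT averages the
    difference of the two counterfactual conditional means (site set to large
    then small, covariates fixed) over the rows assigned to large sites, the
    ATE over all rows.
    """
    model = config.outcome(outcome)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(9,)))
    C = _draw_covariates(config, n_mc, rng)
    site = (rng.random(n_mc) < expit(_site_logit(config, C))).astype(int)
    diff = conditional_mean(config, model, C, 1) - conditional_mean(config, model, C, 0)
    treated = diff[site == 1]
    if len(treated) == 0:
        raise ValueError("no treated rows drawn; site model is degenerate")
    return TruthReport(
        outcome=outcome,
        ett=float(np.mean(treated)),
        ett_mc_se=float(np.std(treated, ddof=1) / np.sqrt(len(treated))),
        ate=float(np.mean(diff)),
        ate_mc_se=float(np.std(diff, ddof=1) / np.sqrt(n_mc)),
        n_mc=n_mc,
    )


# ---------------------------------------------------------------------------
# discrete oracle fixture
# ---------------------------------------------------------------------------

@dataclass
class DiscreteToy:
    """Cohort with one binary covariate plus the probability table that
    generated it, so the ETT has a closed form."""

    cohort: CohortTable
    p_w: float  # P(W = 1)
    p_s_given_w: tuple[float, float]  # P(S=1 | W=0), P(S=1 | W=1)
    p_y: dict[tuple[int, int], float]  # (s, w) -> P(Y=1 | S=s, W=w)

    @property
    def closed_form_ett(self) -> float:
        """psi0 = sum_w [P(Y|S=1,w) - P(Y|S=0,w)] P(w | S=1)."""
        p_w1_s1 = self.p_s_given_w[1] * self.p_w
        p_w0_s1 = self.p_s_given_w[0] * (1.0 - self.p_w)
        total = p_w1_s1 + p_w0_s1
        psi = 0.0
        for w, p_cond in ((0, p_w0_s1 / total), (1, p_w1_s1 / total)):
            psi += (self.p_y[(1, w)] - self.p_y[(0, w)]) * p_cond
        return psi


def make_discrete_toy(
    n: int,
    seed: int,
    p_w: float = 0.4,
    p_s_given_w: tuple[float, float] = (0.35, 0.65),
    p_y: dict[tuple[int, int], float] | None = None,
) -> DiscreteToy:
    """Small discrete cohort (binary W, S, Y) with all probabilities strictly
    inside (0.1, 0.9), used as an enumeration oracle for the estimators."""
    if n < 50:
        raise ValueError("toy cohort needs n >= 50")
    if p_y is None:
        p_y = {(0, 0): 0.20, (0, 1): 0.50, (1, 0): 0.30, (1, 1): 0.65}
    for label, p in [("p_w", p_w), *[(f"p_s|w={w}", v) for w, v in enumerate(p_s_given_w)],
                     *[(f"p_y{k}", v) for k, v in p_y.items()]]:
        if not 0.1 < p < 0.9:
            raise ValueError(f"probability {label}={p} outside (0.1, 0.9)")
    rng = np.random.default_rng(seed)
    w = (rng.random(n) < p_w).astype(int)
    s = (rng.random(n) < np.where(w == 1, p_s_given_w[1], p_s_given_w[0])).astype(int)
    py = np.array([p_y[(si, wi)] for si, wi in zip(s, w)])
    y = (rng.random(n) < py).astype(float)
    df = pd.DataFrame({ID_COL: np.arange(n), SITE_COL: s, "y": y, "w": w.astype(float)})
    cohort = CohortTable(df, outcomes={"y": "binary"}, covariates={"w": "binary"})
    return DiscreteToy(cohort=cohort, p_w=p_w, p_s_given_w=p_s_given_w, p_y=p_y)
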