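"""End-to-end orchestration: simulate/load -> summarize -> fit -> estimate ->
diagnose -> report, driven by a validated run configuration."""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, plots
from .cohort import SITE_COL, CohortTable
from .config import ConfigurationError, GeneratorConfig
from .estimators import (
    ETTEstimate,
    fit_outcome_model,
    fit_propensity,
    matching_ett,
    substitution_ett,
    tmle_ett,
    unadjusted_difference,
)
from .inference import bootstrap_ci
from .preprocess import bivariate_summary, expand_missingness, format_summary_table
from .simulate import default_config, generate_cohort, true_ett
from .superlearner import LearnerSpec, default_library

logger = logging.getLogger(__name__)

KNOWN_ESTIMATORS = [
    "unadjusted",
    "substitution-regression",
    "substitution-SL",
    "tmle",
    "matching",
]

_RUNCONFIG_FIELDS = {
    "input_csv", "generator", "outcomes", "outcome_types", "covariate_types",
    "estimators", "sl_library", "K", "delta", "caliper_sd", "B",
    "bootstrap_mode", "tol", "max_iter", "seed", "n_mc_truth", "output_dir",
}

_LIBRARY_NAMES = {s.name: s for s in default_library()}


@dataclass
class RunConfig:
    """Fully resolved pipeline configuration.

    Exactly one of ``input_csv`` / ``generator`` supplies the cohort.  CSV
    input additionally needs ``outcome_types`` and ``covariate_types``
    declarations (column name -> type)."""

    input_csv: str | None = None
    generator: GeneratorConfig | None = None
    outcomes: list[str] = field(default_factory=list)  # empty -> all declared
    outcome_types: dict[str, str] = field(default_factory=dict)
    covariate_types: dict[str, str] = field(default_factory=dict)
    estimators: list[str] = field(default_factory=lambda: list(KNOWN_ESTIMATORS))
    sl_library: list[str] = field(default_factory=lambda: list(_LIBRARY_NAMES))
    K: int = 10
    delta: float = 0.025
    caliper_sd: float = 0.05
    B: int = 1000
    bootstrap_mode: str = "refit"  # refit (honest) | fixed (fast, approximate)
    tol: float = 1e-5
    max_iter: int = 50
    seed: int = 7
    n_mc_truth: int = 1_000_000
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ConfigurationError(
                "exactly one of input_csv / generator must be given")
        unknown = set(self.estimators) - set(KNOWN_ESTIMATORS)
        if unknown:
            raise ConfigurationError(
                f"estimators: unknown labels {sorted(unknown)}; "
                f"known: {KNOWN_ESTIMATORS}")
        unknown_l = set(self.sl_library) - set(_LIBRARY_NAMES)
        if unknown_l:
            raise ConfigurationError(
                f"sl_library: unknown learners {sorted(unknown_l)}; "
                f"known: {sorted(_LIBRARY_NAMES)}")
        if self.bootstrap_mode not in {"refit", "fixed"}:
            raise ConfigurationError("bootstrap_mode must be 'refit' or 'fixed'")
        if not 0 <= self.delta < 0.5:
            raise ConfigurationError("delta must lie in [0, 0.5)")

    def library(self) -> list[LearnerSpec]:
        return [_LIBRARY_NAMES[name] for name in self.sl_library]

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _RUNCONFIG_FIELDS if k != "generator"}
        d["generator"] = self.generator.to_dict() if self.generator else None
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration; unknown keys are an
    error naming the key."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError("run config must be a mapping")
    unknown = set(raw) - _RUNCONFIG_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if raw.get("generator") is not None:
        raw = dict(raw)
        gen = raw["generator"]
        raw["generator"] = gen if isinstance(gen, GeneratorConfig) \
            else GeneratorConfig.from_dict(gen)
    return RunConfig(**raw)


# ---------------------------------------------------------------------------
# cohort CSV I/O
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    """RFC-4180 CSV, UTF-8, '.' decimal; missing values as empty fields."""
    cohort.df.to_csv(path, index=False, na_rep="")


def read_cohort_csv(
    path: str | Path,
    outcome_types: dict[str, str],
    covariate_types: dict[str, str],
) -> CohortTable:
    """Read a patient-level CSV; empty fields become missing markers.

    The site column must be named ``site_large`` and coded 0/1; declared
    binary outcomes may contain only 0/1 (or be missing)."""
    df = pd.read_csv(path)
    missing_cols = ({SITE_COL} | set(outcome_types) | set(covariate_types)) - set(df.columns)
    if missing_cols:
        raise ConfigurationError(f"input CSV lacks declared columns: {sorted(missing_cols)}")
    site_vals = set(df[SITE_COL].dropna().unique())
    if not site_vals.issubset({0, 1}):
        raise ConfigurationError(
            f"site column {SITE_COL!r} must be coded 0/1; found values {sorted(site_vals)}")
    for name, kind in outcome_types.items():
        if kind == "binary":
            vals = set(df[name].dropna().unique())
            if not vals.issubset({0, 1}):
                raise ConfigurationError(
                    f"outcome {name!r} declared binary but contains {sorted(vals)}")
    return CohortTable(df, outcomes=dict(outcome_types), covariates=dict(covariate_types))


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def estimate_outcome(
    cohort: CohortTable,
    design,
    outcome: str,
    config: RunConfig,
    qfit_cache: dict | None = None,
) -> list[ETTEstimate]:
    """Run the configured estimators for one outcome; returns one estimate
    per requested estimator, bootstrap CIs attached to the substitution
    estimators."""
    mask = cohort.outcome_mask(outcome)
    y = cohort.outcome_values(outcome)[mask]
    S = cohort.site[mask]
    X = design.df.loc[mask].reset_index(drop=True)
    otype = cohort.outcomes[outcome]
    library = config.library()
    results: list[ETTEstimate] = []

    needs_g = {"tmle", "matching"} & set(config.estimators)
    gfit = None
    if needs_g:
        gfit = fit_propensity(X, S, method="superlearner", library=library,
                              delta=config.delta, K=config.K, seed=config.seed)

    for est_name in config.estimators:
        t0 = time.time()
        if est_name == "unadjusted":
            results.append(unadjusted_difference(cohort, outcome))
        elif est_name in ("substitution-regression", "substitution-SL"):
            method = "regression" if est_name.endswith("regression") else "superlearner"
            qfit = fit_outcome_model(X, S, y, method=method, outcome_type=otype,
                                     library=library, K=config.K, seed=config.seed)
            point = substitution_ett(X, S, y, qfit, label=est_name)

            if config.bootstrap_mode == "refit":
                def replicate(frame: pd.DataFrame) -> float:
                    Sb = frame[SITE_COL].to_numpy(dtype=int)
                    yb = frame["__y__"].to_numpy(dtype=float)
                    Xb = frame.drop(columns=[SITE_COL, "__y__"])
                    qb = fit_outcome_model(Xb, Sb, yb, method=method,
                                           outcome_type=otype, library=library,
                                           K=config.K, seed=config.seed)
                    return substitution_ett(Xb, Sb, yb, qb).psi
            else:  # fixed-learner mode: approximate, no refit
                def replicate(frame: pd.DataFrame) -> float:
                    Sb = frame[SITE_COL].to_numpy(dtype=int)
                    yb = frame["__y__"].to_numpy(dtype=float)
                    Xb = frame.drop(columns=[SITE_COL, "__y__"])
                    return substitution_ett(Xb, Sb, yb, qfit).psi

            boot_frame = X.copy()
            boot_frame[SITE_COL] = S
            boot_frame["__y__"] = y
            boot = bootstrap_ci(replicate, boot_frame, B=config.B, seed=config.seed)
            results.append(point.with_ci(boot.se))
        elif est_name == "tmle":
            qfit = fit_outcome_model(X, S, y, method="superlearner", outcome_type=otype,
                                     library=library, K=config.K, seed=config.seed)
            est, _state = tmle_ett(X, S, y, qfit, gfit, tol=config.tol,
                                   max_iter=config.max_iter)
            results.append(est)
        elif est_name == "matching":
            est, _matched = matching_ett(S, y, gfit, caliper_sd=config.caliper_sd)
            results.append(est)
        logger.info("%s / %s: %.1fs", outcome, est_name, time.time() - t0)
    return results


def estimates_frame(all_results: dict[str, list[ETTEstimate]]) -> pd.DataFrame:
    rows = []
    for outcome, ests in all_results.items():
        for e in ests:
            rows.append({
                "outcome": outcome, "estimator": e.estimator, "psi": e.psi,
                "se": e.se, "ci_lo": e.ci_lo, "ci_hi": e.ci_hi,
                "n_treated": e.n_treated, "n_discarded": e.n_discarded,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle to
    ``config.output_dir``.  Returns the bundle as a dict of artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    if config.generator is not None:
        cohort = generate_cohort(config.generator, seed=config.seed)
    else:
        cohort = read_cohort_csv(config.input_csv, config.outcome_types,
                                 config.covariate_types)
    outcomes = config.outcomes or list(cohort.outcomes)
    unknown = set(outcomes) - set(cohort.outcomes)
    if unknown:
        raise ConfigurationError(f"unknown outcomes requested: {sorted(unknown)}")

    # resolved config echo + hash
    resolved = config.to_dict()
    cfg_text = yaml.safe_dump(resolved, sort_keys=True)
    (out / "run_config.yaml").write_text(cfg_text)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:12]
    logger.info("run config hash %s, seed %d", cfg_hash, config.seed)

    write_cohort_csv(cohort, out / "cohort.csv")

    # Table-1-style summary
    summary = bivariate_summary(cohort)
    summary.to_csv(out / "summary_by_site.csv", index=False)
    n_small = int((cohort.site == 0).sum())
    n_large = int((cohort.site == 1).sum())
    (out / "summary_by_site.txt").write_text(
        format_summary_table(summary, n_small, n_large) + "\n")

    design = expand_missingness(cohort)

    all_results = {o: estimate_outcome(cohort, design, o, config) for o in outcomes}
    est_df = estimates_frame(all_results)
    est_df.to_csv(out / "estimates.csv", index=False)

    truth = None
    if config.generator is not None:
        truth = {o: true_ett(config.generator, o, n_mc=config.n_mc_truth,
                             seed=config.seed).to_dict() for o in outcomes}
        (out / "truth.json").write_text(json.dumps(truth, indent=2))

    # diagnostics bundle on the first binary outcome (risk axis = overall
    # mortality when available, else that outcome itself)
    binary_outcomes = [o for o in outcomes if cohort.outcomes[o] == "binary"]
    diag = {}
    if binary_outcomes:
        target = binary_outcomes[0]
        risk_outcome = "overall_mortality" if "overall_mortality" in cohort.outcomes \
            else target
        library = config.library()
        mask = cohort.outcome_mask(target) & cohort.outcome_mask(risk_outcome)
        sub = cohort.subset(mask)
        Xd = design.df.loc[mask].reset_index(drop=True)
        qfit = fit_outcome_model(Xd, sub.site, sub.outcome_values(target),
                                 method="superlearner", outcome_type="binary",
                                 library=library, K=config.K, seed=config.seed)
        if risk_outcome == target:
            qfit_mort = qfit
        else:
            qfit_mort = fit_outcome_model(Xd, sub.site, sub.outcome_values(risk_outcome),
                                          method="superlearner", outcome_type="binary",
                                          library=library, K=config.K, seed=config.seed)
        res = diagnostics.counterfactual_residuals(sub, Xd, target, qfit, qfit_mort)
        curves = diagnostics.loess_curves(res)
        part = diagnostics.partition_by_divergence(curves[1], res)
        pd.DataFrame({
            "patient_id": res.ids, "site_large": res.site,
            "residual": res.residual, "risk": res.risk,
        }).to_csv(out / f"residuals_{target}.csv", index=False)
        plots.plot_residual_curves(res, curves, out / f"residuals_{target}.png",
                                   cutoff=part.cutoff)
        hist = diagnostics.risk_histogram(res)
        hist.to_csv(out / "risk_histogram.csv", index=False)
        plots.plot_risk_histogram(hist, out / "risk_histogram.png")
        diag = {"residuals": res, "curves": curves, "partition": part}
        if part.cutoff is not None and len(part.flagged_ids) and len(part.unflagged_ids):
            diagnostics.compare_subgroups(sub, part).to_csv(
                out / f"subgroups_{target}.csv", index=False)

    if "matching" in config.estimators and outcomes:
        o = outcomes[0]
        mask = cohort.outcome_mask(o)
        Xo = design.df.loc[mask].reset_index(drop=True)
        So = cohort.site[mask]
        gfit = fit_propensity(Xo, So, method="superlearner", library=config.library(),
                              delta=config.delta, K=config.K, seed=config.seed)
        _, matched = matching_ett(So, cohort.outcome_values(o)[mask], gfit,
                                  caliper_sd=config.caliper_sd)
        from .preprocess import DesignMatrix

        bal = diagnostics.matched_balance(
            matched, DesignMatrix(Xo, design.continuous_cols, design.binary_cols), So)
        bal.smd.to_csv(out / "balance_smd.csv", index=False)
        plots.plot_balance_heatmap(bal, out / "balance_heatmap.png")
        diag["balance"] = bal

    log = {
        "seed": config.seed, "config_hash": cfg_hash,
        "wall_time_s": round(time.time() - t_start, 2),
        "n_patients": cohort.n, "n_small": n_small, "n_large": n_large,
        "outcomes": outcomes, "estimators": config.estimators,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {"cohort": cohort, "summary": summary, "estimates": est_df,
            "truth": truth, "diagnostics": diag, "log": log}
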