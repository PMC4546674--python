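"""Declarative configuration for the synthetic cohort generator.

A :class:`GeneratorConfig` fully specifies the data-generating mechanism:
covariate marginals, a logistic site-assignment model on standardized
covariates, per-covariate logistic missingness models, and outcome models
(Bernoulli-logit or gamma/lognormal log-linear) with a site main effect and
site-by-covariate interactions.  Configs round-trip through YAML/JSON so a
run's mechanism is a recordable artifact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

VALID_DISTRIBUTIONS = {
    "normal",  # params: mean, sd
    "truncated_normal",  # params: mean, sd, lower, upper
    "truncated_gamma",  # params: mean, sd, lower, upper
    "bernoulli",  # params: p
}
VALID_OUTCOME_FAMILIES = {
    "bernoulli-logit",
    "gamma-loglinear",
    "lognormal-loglinear",
    "normal-identity",
}


class ConfigurationError(ValueError):
    """Invalid generator or run configuration."""


@dataclass
class CovariateSpec:
    name: str
    distribution: str
    params: dict[str, float]
    kind: str = "continuous"  # continuous | binary

    def __post_init__(self) -> None:
        if self.distribution not in VALID_DISTRIBUTIONS:
            raise ConfigurationError(
                f"unknown distribution {self.distribution!r} for covariate "
                f"{self.name!r}; valid: {sorted(VALID_DISTRIBUTIONS)}"
            )
        if self.distribution == "bernoulli" and self.kind != "binary":
            raise ConfigurationError(f"bernoulli covariate {self.name!r} must be binary")

    @property
    def center(self) -> float:
        """Location used to standardize this covariate inside linear predictors."""
        return 0.0 if self.kind == "binary" else float(self.params["mean"])

    @property
    def scale(self) -> float:
        return 1.0 if self.kind == "binary" else float(self.params["sd"])


@dataclass
class SiteModel:
    """logit P(site=large | C) = intercept + coef . standardized(C)."""

    intercept: float = 0.0
    coefficients: dict[str, float] = field(default_factory=dict)


@dataclass
class MissingnessModel:
    """logit P(covariate missing | site, C) for one covariate.

    ``self_coefficient`` (default 0) multiplies the covariate's own
    standardized, pre-masking value: nonzero makes the mechanism MNAR.
    """

    covariate: str
    intercept: float
    site_coefficient: float = 0.0
    coefficients: dict[str, float] = field(default_factory=dict)
    self_coefficient: float = 0.0


@dataclass
class OutcomeModel:
    """One outcome: linear predictor on standardized covariates with a site
    main effect and optional site-by-covariate interactions."""

    name: str
    family: str
    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    site_coefficient: float = 0.0
    interactions: dict[str, float] = field(default_factory=dict)  # site x covariate
    shape: float = 1.0  # gamma shape / lognormal sigma / normal residual SD

    def __post_init__(self) -> None:
        if self.family not in VALID_OUTCOME_FAMILIES:
            raise ConfigurationError(
                f"unknown outcome family {self.family!r} for {self.name!r}; "
                f"valid: {sorted(VALID_OUTCOME_FAMILIES)}"
            )

    @property
    def outcome_type(self) -> str:
        return "binary" if self.family == "bernoulli-logit" else "continuous"


@dataclass
class GeneratorConfig:
    n_patients: int
    covariates: list[CovariateSpec]
    site_model: SiteModel
    missingness: list[MissingnessModel] = field(default_factory=list)
    outcomes: list[OutcomeModel] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be at least 2")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate covariate names")
        known = set(names)
        for coef_name in self.site_model.coefficients:
            if coef_name not in known:
                raise ConfigurationError(
                    f"site model references unknown covariate {coef_name!r}"
                )
        for mm in self.missingness:
            if mm.covariate not in known:
                raise ConfigurationError(
                    f"missingness model for unknown covariate {mm.covariate!r}"
                )
            for coef_name in mm.coefficients:
                if coef_name not in known:
                    raise ConfigurationError(
                        f"missingness model for {mm.covariate!r} references "
                        f"unknown covariate {coef_name!r}"
                    )
        out_names = [o.name for o in self.outcomes]
        if len(set(out_names)) != len(out_names):
            raise ConfigurationError("duplicate outcome names")
        for om in self.outcomes:
            for coef_name in list(om.coefficients) + list(om.interactions):
                if coef_name not in known:
                    raise ConfigurationError(
                        f"outcome {om.name!r} references unknown covariate {coef_name!r}"
                    )

    def covariate(self, name: str) -> CovariateSpec:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def outcome(self, name: str) -> OutcomeModel:
        for o in self.outcomes:
            if o.name == name:
                return o
        raise ConfigurationError(
            f"unknown outcome {name!r}; declared: {[o.name for o in self.outcomes]}"
        )

    # -- serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(
            n_patients=int(d["n_patients"]),
            covariates=[CovariateSpec(**c) for c in d["covariates"]],
            site_model=SiteModel(**d.get("site_model", {})),
            missingness=[MissingnessModel(**m) for m in d.get("missingness", [])],
            outcomes=[OutcomeModel(**o) for o in d.get("outcomes", [])],
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))
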