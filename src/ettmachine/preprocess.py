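"""Design-matrix construction and bivariate cohort summaries.

Missing covariates are handled by the indicator method rather than
imputation: every sometimes-missing covariate C_j contributes an
observedness indicator Delta_j (1 = observed) and the product Delta_j * C_j
(zero where missing), yielding a fully observed basis whose missingness
information is available to all downstream model fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SITE_COL, CohortTable

__all__ = [
    "DesignMatrix",
    "ScalingParams",
    "expand_missingness",
    "standardize",
    "apply_scaling",
    "bivariate_summary",
    "format_summary_table",
    "two_proportion_z",
]

DELTA_PREFIX = "delta_"


@dataclass
class DesignMatrix:
    """Fully observed basis aligned row-for-row with its source cohort."""

    df: pd.DataFrame
    continuous_cols: list[str] = field(default_factory=list)
    binary_cols: list[str] = field(default_factory=list)  # incl. Delta indicators

    def __post_init__(self) -> None:
        if self.df.isna().any().any():
            bad = self.df.columns[self.df.isna().any()].tolist()
            raise ValueError(f"design matrix contains missing entries in {bad}")

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def to_numpy(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)


def expand_missingness(cohort: CohortTable) -> DesignMatrix:
    """Build the indicator-method basis from a cohort.

    Never-missing covariates pass through as a single column; sometimes-missing
    covariates become the (Delta_j, Delta_j*C_j) pair.  Categorical covariates
    are expanded to reference-coded indicators (modal category as reference)
    before the indicator step.
    """
    if cohort.n == 0:
        raise ValueError("empty cohort")
    pieces: dict[str, np.ndarray] = {}
    continuous: list[str] = []
    binary: list[str] = []

    def add_column(name: str, values: pd.Series, kind: str) -> None:
        observed = values.notna()
        if not observed.any():
            raise ValueError(f"covariate {name!r} is entirely missing")
        if observed.all():
            pieces[name] = values.to_numpy(dtype=float)
            (continuous if kind == "continuous" else binary).append(name)
        else:
            delta = observed.to_numpy().astype(float)
            pieces[DELTA_PREFIX + name] = delta
            pieces[name] = np.where(observed, values.to_numpy(dtype=float), 0.0)
            binary.append(DELTA_PREFIX + name)
            (continuous if kind == "continuous" else binary).append(name)

    for name, kind in cohort.covariates.items():
        col = cohort.df[name]
        if kind == "categorical":
            observed = col.dropna()
            if observed.empty:
                raise ValueError(f"covariate {name!r} is entirely missing")
            reference = observed.mode().iloc[0]
            for level in sorted(set(observed) - {reference}, key=str):
                indicator = col.map(lambda v: np.nan if pd.isna(v) else float(v == level))
                add_column(f"{name}__{level}", indicator, "binary")
        else:
            add_column(name, col, kind)

    df = pd.DataFrame(pieces, index=cohort.df.index)
    return DesignMatrix(df, continuous_cols=continuous, binary_cols=binary)


@dataclass
class ScalingParams:
    center: dict[str, float]
    scale: dict[str, float]


def standardize(design: DesignMatrix) -> tuple[DesignMatrix, ScalingParams]:
    """Z-score continuous columns; binary and Delta columns pass through.

    Zero-variance continuous columns are left unscaled with a warning.
    Returns the scaled matrix and the parameters for reuse on new rows.
    """
    if len(design.df) == 0:
        raise ValueError("empty design matrix")
    center: dict[str, float] = {}
    scale: dict[str, float] = {}
    for col in design.continuous_cols:
        x = design.df[col].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if sd == 0.0:
            warnings.warn(f"column {col!r} has zero variance; left unscaled", stacklevel=2)
            center[col], scale[col] = 0.0, 1.0
        else:
            center[col], scale[col] = float(np.mean(x)), sd
    params = ScalingParams(center=center, scale=scale)
    return apply_scaling(design, params), params


def apply_scaling(design: DesignMatrix, params: ScalingParams) -> DesignMatrix:
    df = design.df.copy()
    for col, mu in params.center.items():
        df[col] = (df[col] - mu) / params.scale[col]
    return DesignMatrix(df, list(design.continuous_cols), list(design.binary_cols))


# ---------------------------------------------------------------------------
# bivariate summaries
# ---------------------------------------------------------------------------

def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion Z test; returns (z, two-sided p)."""
    if min(n1, n2) == 0:
        raise ValueError("empty group")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    denom = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if denom == 0:
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(denom)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U via the normal approximation with tie correction and no
    continuity correction."""
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    return float(res.pvalue)


def bivariate_summary(cohort: CohortTable) -> pd.DataFrame:
    """Per-variable by-site summary table.

    Continuous variables: mean (SD) per site and a rank-sum (Mann-Whitney U)
    p-value on observed values.  Binary variables (including each covariate's
    missingness indicator): percent per site and a pooled two-proportion Z
    p-value.  Site groups are labeled small (site=0) and large (site=1).
    """
    site = cohort.site
    if not (np.any(site == 0) and np.any(site == 1)):
        raise ValueError("both site levels must be present")
    rows = []
    variables = [(name, kind) for name, kind in cohort.covariates.items()]
    variables += [(name, kind) for name, kind in cohort.outcomes.items()]

    def summarize(name: str, values: pd.Series, kind: str) -> None:
        obs = values.notna().to_numpy()
        small = values[(site == 0) & obs].to_numpy(dtype=float)
        large = values[(site == 1) & obs].to_numpy(dtype=float)
        if kind == "binary":
            z, p = two_proportion_z(int(small.sum()), len(small), int(large.sum()), len(large))
            rows.append({
                "variable": name, "type": "binary",
                "small": 100 * small.mean(), "large": 100 * large.mean(),
                "small_sd": np.nan, "large_sd": np.nan,
                "p_value": p, "test": "two-proportion Z",
            })
        else:
            rows.append({
                "variable": name, "type": "continuous",
                "small": small.mean(), "large": large.mean(),
                "small_sd": small.std(ddof=1), "large_sd": large.std(ddof=1),
                "p_value": _rank_sum_p(small, large), "test": "Mann-Whitney U",
            })
        miss = values.isna().to_numpy()
        if miss.any():
            z, p = two_proportion_z(
                int(miss[site == 0].sum()), int((site == 0).sum()),
                int(miss[site == 1].sum()), int((site == 1).sum()),
            )
            rows.append({
                "variable": f"{name} missing", "type": "binary",
                "small": 100 * miss[site == 0].mean(), "large": 100 * miss[site == 1].mean(),
                "small_sd": np.nan, "large_sd": np.nan,
                "p_value": p, "test": "two-proportion Z",
            })

    for name, kind in variables:
        col = cohort.df[name]
        if kind == "categorical":
            for level in sorted(col.dropna().unique(), key=str):
                summarize(f"{name}={level}", col.map(
                    lambda v: np.nan if pd.isna(v) else float(v == level)), "binary")
        else:
            summarize(name, col, "binary" if kind == "binary" else "continuous")
    return pd.DataFrame(rows)


def format_summary_table(summary: pd.DataFrame, n_small: int, n_large: int) -> str:
    """Monospaced rendering of the by-site summary (variable, small, large, p)."""
    lines = [
        f"{'Variable':<28}{f'Small (n={n_small})':>20}{f'Large (n={n_large})':>20}{'p':>10}",
        "-" * 78,
    ]
    for _, r in summary.iterrows():
        if r["type"] == "binary":
            small = f"{r['small']:.1f}%"
            large = f"{r['large']:.1f}%"
        else:
            small = f"{r['small']:.1f} ({r['small_sd']:.1f})"
            large = f"{r['large']:.1f} ({r['large_sd']:.1f})"
        lines.append(f"{r['variable']:<28}{small:>20}{large:>20}{r['p_value']:>10.3f}")
    return "\n".join(lines)
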