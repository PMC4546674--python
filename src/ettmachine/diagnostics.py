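"""Interpretability layer for the ETT machinery.

Counterfactual residuals — the observed outcome minus the model's prediction
at the opposite site value — decompose an estimated effect across patients.
Plotted against a common risk axis (predicted overall mortality with site set
to large for every patient) they show whether an effect is absent, uniform,
or concentrated in a risk stratum; a divergence-region rule then turns the
visual "where do the curves leave zero" into a reproducible patient subgroup.
Matched-set balance is examined with scaled covariates, hierarchical
clustering, and standardized mean differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .cohort import CohortTable
from .estimators import MatchedSet, OutcomeFit
from .preprocess import DesignMatrix, standardize

__all__ = [
    "ResidualSet",
    "LoessCurve",
    "SubgroupPartition",
    "BalanceReport",
    "counterfactual_residuals",
    "loess_smooth",
    "loess_curves",
    "partition_by_divergence",
    "compare_subgroups",
    "matched_balance",
    "risk_histogram",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# counterfactual residuals
# ---------------------------------------------------------------------------

@dataclass
class ResidualSet:
    """Per-patient counterfactual residual r_i = Y_i - Qbar(1 - S_i, C_i) and
    risk score x_i (predicted overall mortality at the large-site value)."""

    outcome: str
    ids: np.ndarray
    site: np.ndarray
    residual: np.ndarray
    risk: np.ndarray
    n_excluded: int = 0

    def group(self, site_value: int) -> tuple[np.ndarray, np.ndarray]:
        m = self.site == site_value
        return self.risk[m], self.residual[m]


def counterfactual_residuals(
    cohort: CohortTable,
    design: DesignMatrix | pd.DataFrame,
    outcome: str,
    qfit_outcome: OutcomeFit,
    qfit_mortality: OutcomeFit,
) -> ResidualSet:
    """Residuals of every patient against their opposite-site prediction.

    The mean residual over the large-site group is algebraically the
    substitution ETT estimate for the outcome.  Rows with a missing outcome
    are excluded (logged)."""
    y = cohort.outcome_values(outcome)
    mask = cohort.outcome_mask(outcome)
    n_excluded = int((~mask).sum())
    if n_excluded:
        logger.info("counterfactual residuals: excluded %d rows with missing %r",
                    n_excluded, outcome)
    X = design.df if isinstance(design, DesignMatrix) else pd.DataFrame(design)
    site = cohort.site
    q_opposite = np.where(site == 1, qfit_outcome.predict(X, 0), qfit_outcome.predict(X, 1))
    risk = qfit_mortality.predict(X, 1)
    return ResidualSet(
        outcome=outcome,
        ids=cohort.df.loc[mask, cohort.df.columns[0]].to_numpy(),
        site=site[mask],
        residual=(y - q_opposite)[mask],
        risk=risk[mask],
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# loess
# ---------------------------------------------------------------------------

@dataclass
class LoessCurve:
    grid: np.ndarray
    value: np.ndarray
    band_half_width: np.ndarray
    span: float
    site_value: int | None = None


def loess_smooth(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    n_grid: int = 100,
    grid: np.ndarray | None = None,
) -> LoessCurve:
    """Local-linear smooth with tricube weights on an evaluation grid inside
    the observed x range, with an exploratory pointwise band from the local
    weighted residual variance."""
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 points to smooth")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    k = max(int(np.ceil(span * len(x))), 3)
    value = np.empty(len(grid))
    half = np.empty(len(grid))
    z975 = stats.norm.ppf(0.975)
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.partition(d, k - 1)[k - 1]
        h = max(h, 1e-12)
        w = np.clip(1 - (d / h) ** 3, 0, None) ** 3
        active = w > 0
        Xl = np.column_stack([np.ones(active.sum()), x[active] - g])
        W = w[active]
        A = (Xl.T * W) @ Xl
        b = (Xl.T * W) @ y[active]
        try:
            coef = np.linalg.solve(A, b)
            lvec = np.linalg.solve(A, (Xl.T * W))[0]  # smoother weights at g
        except np.linalg.LinAlgError:
            coef = np.array([np.average(y[active], weights=W), 0.0])
            lvec = W / W.sum()
        value[i] = coef[0]
        resid = y[active] - (coef[0] + coef[1] * (x[active] - g))
        sigma2 = np.sum(W * resid**2) / max(np.sum(W), 1e-12)
        half[i] = z975 * np.sqrt(max(sigma2, 0.0) * np.sum(lvec**2))
    return LoessCurve(grid=grid, value=value, band_half_width=half, span=span)


def loess_curves(
    residuals: ResidualSet, span: float = 0.75, n_grid: int = 100
) -> dict[int, LoessCurve]:
    """One smoothed residual-vs-risk curve per site group, on a shared grid.

    The pointwise bands are exploratory only; they are not reliable
    post-hoc inference."""
    grid = np.linspace(residuals.risk.min(), residuals.risk.max(), n_grid)
    curves = {}
    for s in (0, 1):
        xg, rg = residuals.group(s)
        if len(xg) < 10:
            raise ValueError(f"site group {s} has fewer than 10 points")
        curve = loess_smooth(xg, rg, span=span, grid=grid)
        curve.site_value = s
        curves[s] = curve
    return curves


# ---------------------------------------------------------------------------
# divergence region
# ---------------------------------------------------------------------------

@dataclass
class SubgroupPartition:
    cutoff: float | None  # None when the curve never leaves the threshold band
    site_value: int
    flagged_ids: np.ndarray
    unflagged_ids: np.ndarray
    flagged_positive_ids: np.ndarray  # residual > 0 within the flagged region
    flagged_negative_ids: np.ndarray


def partition_by_divergence(
    curve: LoessCurve,
    residuals: ResidualSet,
    threshold: float | None = None,
    site_value: int = 1,
    persistence: float = 0.10,
) -> SubgroupPartition:
    """Split one site group at the risk value where its smoothed residual
    curve starts to diverge from zero.

    The cutoff is the smallest grid point whose |smoothed value| exceeds the
    threshold and where at least ``persistence`` of the remaining grid also
    exceeds it (a single noisy spike does not open a region).  Patients of
    the site group at or beyond the cutoff are flagged and split by residual
    sign.  A curve that never exceeds the threshold yields an empty region.
    ``threshold`` defaults to half the pointwise band half-width at the grid
    median."""
    if threshold is None:
        threshold = 0.5 * float(np.median(curve.band_half_width))
    exceed = np.abs(curve.value) > threshold
    cutoff = None
    for i in np.flatnonzero(exceed):
        if np.mean(exceed[i:]) >= max(persistence, 1e-12):
            cutoff = float(curve.grid[i])
            break
    x, r = residuals.group(site_value)
    ids = residuals.ids[residuals.site == site_value]
    if cutoff is None:
        flagged = np.zeros(len(ids), dtype=bool)
    else:
        flagged = x >= cutoff
    return SubgroupPartition(
        cutoff=cutoff,
        site_value=site_value,
        flagged_ids=ids[flagged],
        unflagged_ids=ids[~flagged],
        flagged_positive_ids=ids[flagged & (r > 0)],
        flagged_negative_ids=ids[flagged & (r <= 0)],
    )


def compare_subgroups(cohort: CohortTable, partition: SubgroupPartition) -> pd.DataFrame:
    """Flagged-vs-unflagged comparison of every covariate and outcome.

    Ordered (continuous) variables: Welch t-test; binary variables: Pearson
    chi-square without continuity correction.  Degenerate 2x2 margins report
    p = 1 with a warning."""
    id_col = cohort.df.columns[0]
    in_flag = cohort.df[id_col].isin(partition.flagged_ids).to_numpy()
    in_unflag = cohort.df[id_col].isin(partition.unflagged_ids).to_numpy()
    if not in_flag.any() or not in_unflag.any():
        raise ValueError("both subgroups must be nonempty")
    rows = []
    variables = list(cohort.covariates.items()) + list(cohort.outcomes.items())
    for name, kind in variables:
        col = cohort.df[name]
        a = col[in_flag].dropna().to_numpy(dtype=float)
        b = col[in_unflag].dropna().to_numpy(dtype=float)
        if kind in ("binary", "categorical"):
            table = np.array([
                [np.sum(a == 1), np.sum(a != 1)],
                [np.sum(b == 1), np.sum(b != 1)],
            ])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                warnings.warn(f"degenerate 2x2 margin for {name!r}; p set to 1",
                              stacklevel=2)
                stat, p = 0.0, 1.0
            elif (table.sum(axis=0) == table.sum()).any() or \
                 np.allclose(table[0] / table[0].sum(), table[1] / table[1].sum()):
                stat, p = 0.0, 1.0
            else:
                stat, p, *_ = stats.chi2_contingency(table, correction=False)
            test = "chi-square"
        else:
            if len(a) < 2 or len(b) < 2 or (np.std(a) == 0 and np.std(b) == 0):
                warnings.warn(f"degenerate comparison for {name!r}; p set to 1",
                              stacklevel=2)
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.ttest_ind(a, b, equal_var=False)
            test = "Welch t"
        rows.append({
            "variable": name,
            "flagged_mean": a.mean() if len(a) else np.nan,
            "flagged_sd": a.std(ddof=1) if len(a) > 1 else np.nan,
            "unflagged_mean": b.mean() if len(b) else np.nan,
            "unflagged_sd": b.std(ddof=1) if len(b) > 1 else np.nan,
            "statistic": float(stat),
            "p_value": float(p),
            "test": test,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# matched-set balance
# ---------------------------------------------------------------------------

@dataclass
class BalanceReport:
    scaled: pd.DataFrame  # scaled covariates of the matched rows
    site: np.ndarray  # site label per matched row
    row_order: np.ndarray  # dendrogram leaf order
    linkage_matrix: np.ndarray
    cluster_labels: np.ndarray  # 2-cluster cut
    cluster_site_chi2: float
    cluster_site_p: float
    smd: pd.DataFrame  # per-covariate SMD before/after matching


def _smd(x1, x0, pooled_sd, w1=None, w0=None):
    m1 = np.average(x1, weights=w1)
    m0 = np.average(x0, weights=w0)
    return (m1 - m0) / pooled_sd if pooled_sd > 0 else 0.0


def matched_balance(
    matched: MatchedSet, design: DesignMatrix, S: np.ndarray
) -> BalanceReport:
    """Balance assessment of the matched set.

    Covariates are scaled (continuous z-scored, binary untouched), matched
    rows are clustered hierarchically (Euclidean distance, average linkage),
    and a 2-cluster cut is tested for association with the site label: a
    successful match shows covariate clusters that do NOT align with site.
    Standardized mean differences (difference of group means over the
    pre-match pooled SD) are reported before and after matching, with reused
    controls weighted by their reuse count."""
    S = np.asarray(S).astype(int)
    rows = matched.matched_rows
    if len(rows) < 3:
        raise ValueError("need at least 3 matched rows")
    scaled_full, _ = standardize(design)
    sub = scaled_full.df.iloc[rows].reset_index(drop=True)
    site_sub = S[rows]

    Z = linkage(sub.to_numpy(dtype=float), method="average", metric="euclidean")
    from scipy.cluster.hierarchy import leaves_list

    order = leaves_list(Z)
    clusters = fcluster(Z, t=2, criterion="maxclust")
    table = pd.crosstab(clusters, site_sub).to_numpy()
    if table.shape == (2, 2) and (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2, p, *_ = stats.chi2_contingency(table, correction=False)
    else:
        chi2, p = 0.0, 1.0

    # SMDs: pre-match over all rows, post-match with control reuse weights
    controls = np.array(sorted(matched.control_weight), dtype=int)
    w_c = np.array([matched.control_weight[int(j)] for j in controls])
    smd_rows = []
    for col in design.columns:
        x = design.df[col].to_numpy(dtype=float)
        sd_pool = np.sqrt((np.var(x[S == 1], ddof=1) + np.var(x[S == 0], ddof=1)) / 2)
        pre = _smd(x[S == 1], x[S == 0], sd_pool)
        post = _smd(x[matched.treated_idx], x[controls], sd_pool, w0=w_c)
        smd_rows.append({"covariate": col, "smd_pre": pre, "smd_post": post})
    return BalanceReport(
        scaled=sub, site=site_sub, row_order=order, linkage_matrix=Z,
        cluster_labels=clusters, cluster_site_chi2=float(chi2),
        cluster_site_p=float(p), smd=pd.DataFrame(smd_rows),
    )


# ---------------------------------------------------------------------------
# risk histogram
# ---------------------------------------------------------------------------

def risk_histogram(residuals: ResidualSet, bins: int = 20) -> pd.DataFrame:
    """Histogram of the counterfactual mortality-risk scores with shared bin
    edges over [0, 1], one count column per site group."""
    if bins < 2:
        raise ValueError("need at least 2 bins")
    edges = np.linspace(0.0, 1.0, bins + 1)
    out = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    for s in (0, 1):
        x, _ = residuals.group(s)
        counts, _ = np.histogram(np.clip(x, 0, 1), bins=edges)
        out[f"count_site_{s}"] = counts
    return pd.DataFrame(out)
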