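"""Standard errors and Wald-style confidence intervals.

Each estimator gets the inference the theory supports: closed-form two-sample
variance for the unadjusted difference, the nonparametric bootstrap for the
substitution estimators (which re-runs the full model fit on every resample),
the efficient-influence-curve variance for the converged TMLE, and a
reuse-weighted paired variance for matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "wald_ci",
    "BootstrapResult",
    "bootstrap_ci",
    "eif_values",
    "tmle_eif_se",
    "matching_se",
]


def wald_ci(psi: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """psi +/- z * se at the given two-sided coverage level."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf((1 + level) / 2)
    return float(psi - z * se), float(psi + z * se)


# ---------------------------------------------------------------------------
# nonparametric bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    psi: float
    se: float
    ci_lo: float
    ci_hi: float
    replicates: np.ndarray
    n_failed: int


def bootstrap_ci(
    estimator: Callable[[pd.DataFrame], float],
    df: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    stratify_col: str | None = None,
) -> BootstrapResult:
    """Resample rows with replacement, re-run the full estimation procedure on
    each resample, and form a Wald interval centered at the full-data estimate
    with the SD of the replicate estimates as the standard error.

    ``estimator`` maps a resampled data frame to a point estimate and is
    expected to refit every model inside.  Replicates that raise are skipped
    and counted; more than 10% failures is an error."""
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    psi_full = float(estimator(df))
    n = len(df)
    reps = []
    n_failed = 0
    if stratify_col is not None:
        groups = [np.flatnonzero(df[stratify_col].to_numpy() == v)
                  for v in np.unique(df[stratify_col])]
    for _ in range(B):
        if stratify_col is None:
            idx = rng.integers(n, size=n)
        else:
            idx = np.concatenate([g[rng.integers(len(g), size=len(g))] for g in groups])
        sample = df.iloc[idx].reset_index(drop=True)
        try:
            reps.append(float(estimator(sample)))
        except Exception:
            n_failed += 1
    if n_failed > 0.10 * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed")
    if n_failed:
        warnings.warn(f"{n_failed}/{B} bootstrap replicates failed and were skipped",
                      stacklevel=2)
    reps = np.asarray(reps)
    se = float(np.std(reps, ddof=1))
    lo, hi = wald_ci(psi_full, se, level)
    return BootstrapResult(psi=psi_full, se=se, ci_lo=lo, ci_hi=hi,
                           replicates=reps, n_failed=n_failed)


# ---------------------------------------------------------------------------
# TMLE: efficient influence curve
# ---------------------------------------------------------------------------

def eif_values(state) -> np.ndarray:
    """Per-patient estimated efficient influence curve of the ETT at the
    targeted solution:

    D_i = (S_i/p1)(Q1_i - Q0_i - psi)
        + [S_i/p1 - (1-S_i) g_i / ((1-g_i) p1)] (Y_i - Qbar(S_i, C_i))

    evaluated on the (possibly bounded-transformed) outcome scale."""
    S = state.S
    resid = state.y - state.QS
    term1 = (S / state.p1) * (state.Q1 - state.Q0 - state.psi)
    term2 = (S / state.p1 - (1 - S) * state.g / ((1 - state.g) * state.p1)) * resid
    return term1 + term2


def tmle_eif_se(state) -> float:
    """EIF-based standard error sqrt(Var(D)/n), back-scaled to the raw
    outcome units for continuous outcomes.  Requires a converged state."""
    if not state.converged:
        raise RuntimeError(
            "TMLE did not converge; the EIF variance is not trustworthy — "
            "use the nonparametric bootstrap instead"
        )
    d = eif_values(state)
    return float(np.sqrt(np.var(d, ddof=1) / len(d)) * state.scale)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def matching_se(matched, y: np.ndarray, g: np.ndarray) -> float:
    """Reuse-weighted paired variance for matching with replacement.

    With paired differences d_i and control reuse weights
    K_j = sum_i 1{j in M_i}/|M_i|,

        V = sum_i (d_i - psi)^2 / (m(m-1))
            + sum_j max(K_j^2 - K_j, 0) sigma2_j / m^2

    where sigma2_j is a nearest-control-neighbor variance proxy
    (Y_j - Y_nn(j))^2 / 2.  With no control reuse this reduces exactly to the
    ordinary paired-difference standard error; reuse can only inflate it."""
    y = np.asarray(y, dtype=float)
    m = len(matched.treated_idx)
    if m < 2:
        raise ValueError("need at least 2 matched treated rows for a standard error")
    diffs = np.array([
        y[i] - y[tied].mean() for i, tied in zip(matched.treated_idx, matched.matches)
    ])
    psi = diffs.mean()
    var = np.sum((diffs - psi) ** 2) / (m * (m - 1))

    controls = np.array(sorted(matched.control_weight), dtype=int)
    if len(controls) >= 2:
        # conditional outcome variance proxy from each used control's nearest
        # other control on the score scale
        order = np.argsort(g[controls])
        gc = g[controls][order]
        yc = y[controls][order]
        sigma2 = np.empty(len(controls))
        for pos in range(len(controls)):
            if pos == 0:
                nn = 1
            elif pos == len(controls) - 1:
                nn = pos - 1
            else:
                nn = pos - 1 if gc[pos] - gc[pos - 1] <= gc[pos + 1] - gc[pos] else pos + 1
            sigma2[pos] = (yc[pos] - yc[nn]) ** 2 / 2.0
        K = np.array([matched.control_weight[int(j)] for j in controls[order]])
        var += np.sum(np.maximum(K**2 - K, 0.0) * sigma2) / m**2
    return float(np.sqrt(var))
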