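"""Figure rendering for the diagnostics layer (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .diagnostics import BalanceReport, LoessCurve, ResidualSet

__all__ = ["plot_residual_curves", "plot_balance_heatmap", "plot_risk_histogram"]

_BAND_CAVEAT = "bands are exploratory; not reliable post-hoc inference"


def plot_residual_curves(
    residuals: ResidualSet,
    curves: dict[int, LoessCurve],
    path: str | Path,
    cutoff: float | None = None,
) -> None:
    """Smoothed counterfactual residuals vs mortality risk, per site group,
    with exploratory pointwise bands and an optional divergence cutoff."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    styles = {0: ("solid", "small-volume"), 1: ("dotted", "large-volume")}
    for s, curve in curves.items():
        ls, label = styles[s]
        ax.plot(curve.grid, curve.value, linestyle=ls, color="black", label=label)
        ax.fill_between(curve.grid, curve.value - curve.band_half_width,
                        curve.value + curve.band_half_width, alpha=0.15, color="gray")
    if cutoff is not None:
        ax.axvspan(cutoff, float(curves[1].grid[-1]), color="tab:blue", alpha=0.12)
    ax.axhline(0.0, color="red", linewidth=0.8)
    ax.set_xlabel("predicted overall mortality (site set to large)")
    ax.set_ylabel(f"counterfactual residual: {residuals.outcome}")
    ax.set_title(f"Counterfactual residuals — {residuals.outcome}\n({_BAND_CAVEAT})",
                 fontsize=10)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_balance_heatmap(report: BalanceReport, path: str | Path) -> None:
    """Scaled-covariate heatmap of the matched set, rows in dendrogram order
    with a site color bar on the left."""
    order = report.row_order
    data = report.scaled.to_numpy(dtype=float)[order]
    site = report.site[order]
    fig, (ax_bar, ax_hm) = plt.subplots(
        1, 2, figsize=(8, 6), gridspec_kw={"width_ratios": [0.04, 1.0]})
    ax_bar.imshow(site[:, None], aspect="auto", cmap="coolwarm", interpolation="nearest")
    ax_bar.set_xticks([])
    ax_bar.set_yticks([])
    ax_bar.set_ylabel("patients (site color: blue=small, red=large)")
    vmax = np.nanpercentile(np.abs(data), 98)
    im = ax_hm.imshow(data, aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                      interpolation="nearest")
    ax_hm.set_xticks(range(data.shape[1]))
    ax_hm.set_xticklabels(report.scaled.columns, rotation=90, fontsize=7)
    ax_hm.set_yticks([])
    fig.colorbar(im, ax=ax_hm, shrink=0.6, label="scaled value")
    fig.suptitle("Matched set, hierarchically clustered", fontsize=11)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_risk_histogram(hist, path: str | Path) -> None:
    """Stacked per-site histogram of counterfactual mortality risks."""
    fig, ax = plt.subplots(figsize=(7, 4))
    width = hist["bin_right"] - hist["bin_left"]
    ax.bar(hist["bin_left"], hist["count_site_0"], width=width, align="edge",
           label="small-volume", color="tab:purple", alpha=0.8)
    ax.bar(hist["bin_left"], hist["count_site_1"], width=width, align="edge",
           bottom=hist["count_site_0"], label="large-volume", color="tab:blue", alpha=0.8)
    ax.set_xlabel("counterfactual predicted probability of overall mortality")
    ax.set_ylabel("patients")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
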