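"""Stability-curve, parallel-analysis and loading plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .baselines import RankDiagnostics
from .stability import StabilityResult

_PANELS = (
    ("ari", "Adjusted Rand index", "higher = more stable"),
    ("vi", "Variation of information", "lower = more stable"),
    ("concordance", "Concordance index", "higher = more stable"),
    ("err_increase", "Transfer-error increase", "lower = more generalizable"),
)


def stability_curves(result: StabilityResult):
    """2x2 panel of per-rank stability/generalizability curves with
    5th-95th percentile bands."""
    summ = result.summary()
    ranks = summ.index.to_numpy()
    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharex=True)
    for ax, (metric, title, note) in zip(axes.ravel(), _PANELS):
        mean = summ[(metric, "mean")]
        lo = summ[(metric, "p05")]
        hi = summ[(metric, "p95")]
        ax.fill_between(ranks, lo, hi, alpha=0.25, lw=0)
        ax.plot(ranks, mean, "o-")
        ax.set_title(title, fontsize=10)
        ax.set_xlabel("number of factors")
        ax.text(0.02, 0.02, note, transform=ax.transAxes, fontsize=7, color="gray")
    fig.tight_layout()
    return fig


def parallel_analysis_plot(diag: RankDiagnostics):
    """Observed eigenvalues against simulated-threshold curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    pos = np.arange(1, diag.eigenvalues.size + 1)
    ax.plot(pos, diag.eigenvalues, "o-", label="observed")
    if diag.pa_thresholds is not None:
        ax.plot(pos, diag.pa_thresholds, "s--", label=f"simulated p{diag.percentile:g}")
    if diag.k_parallel is not None:
        ax.axvline(diag.k_parallel + 0.5, color="gray", lw=0.8)
        ax.set_title(f"parallel analysis retains {diag.k_parallel} factor(s)", fontsize=10)
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def loading_heatmap(loadings: np.ndarray, item_labels: list[str], title: str = ""):
    """Items x factors heatmap with the strongest loading per item marked."""
    L = np.asarray(loadings, float)
    fig, ax = plt.subplots(figsize=(4 + 0.5 * L.shape[1], 0.35 * L.shape[0] + 1.5))
    vmax = np.abs(L).max()
    im = ax.imshow(L, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    for i, j in enumerate(np.argmax(np.abs(L), axis=1)):
        ax.scatter(j, i, marker="*", color="k", s=30)
    ax.set_yticks(range(L.shape[0]), item_labels, fontsize=7)
    ax.set_xticks(range(L.shape[1]), [f"F{j + 1}" for j in range(L.shape[1])])
    if title:
        ax.set_title(title, fontsize=10)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    return fig
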