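"""Figure helpers: ratio-distribution histograms with demarcation guides and
a clustered strain heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

from .clustering import LinkageResult
from .dosage import RatioDistribution

__all__ = ["plot_ratio_distribution", "plot_strain_heatmap"]

_DEMARCATION_COLORS = {"dosage": "red", "compensation": "black", "inverse": "gold"}


def plot_ratio_distribution(dist: RatioDistribution, path: str | Path, title: str | None = None):
    """Bar histogram of an expression-ratio distribution with vertical lines
    at the 1.50 / 1.00 / 0.67 demarcations."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(
        dist.bin_edges[:-1], dist.counts, width=dist.bin_width,
        align="edge", color="#4878a8", edgecolor="white", linewidth=0.3,
    )
    for name, x in dist.demarcations.items():
        ax.axvline(x, color=_DEMARCATION_COLORS.get(name, "grey"),
                   linestyle="--", linewidth=1, label=f"{name} ({x:.2f})")
    ax.set_xlabel("expression ratio (aneuploid / diploid)")
    ax.set_ylabel("genes per bin")
    ax.set_title(title or dist.subset_label)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_strain_heatmap(values, result: LinkageResult, path: str | Path):
    """Heatmap of row-scaled expression over the dysregulated panel with the
    strain dendrogram on top.  ``values`` is the genes × strains matrix the
    clustering was computed on (columns in ``result.labels`` order)."""
    order = [result.labels.index(s) for s in result.leaf_order]
    x = np.asarray(values, dtype=float)[:, order]
    fig, (ax_d, ax_h) = plt.subplots(
        2, 1, figsize=(max(4, 0.7 * len(order)), 7),
        gridspec_kw={"height_ratios": [1, 4]},
    )
    hierarchy.dendrogram(result.linkage_matrix, labels=list(result.labels),
                         ax=ax_d, color_threshold=0)
    ax_d.set_yticks([])
    im = ax_h.imshow(x, aspect="auto", cmap="RdBu_r", interpolation="nearest")
    ax_h.set_xticks(range(len(order)))
    ax_h.set_xticklabels(result.leaf_order, rotation=90, fontsize=7)
    ax_h.set_yticks([])
    ax_h.set_ylabel(f"{x.shape[0]} dysregulated genes")
    fig.colorbar(im, ax=ax_h, shrink=0.6, label="row z-score of log2(FPKM+1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
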