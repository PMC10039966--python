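"""Hierarchical clustering of strains on the union of dysregulated genes.

Strains are embedded as vectors of row-scaled log2(mean FPKM + 1) over the
panel of genes dysregulated in at least one contrast, then clustered
agglomeratively (euclidean distance, complete linkage by default — the
defaults of the common clustered-heatmap tools).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .differential import mean_expression
from .io import ExpressionMatrix, SampleSheet

__all__ = ["LinkageResult", "dysregulated_union", "cluster_strains"]


def dysregulated_union(deg_tables: Mapping[str, pd.DataFrame]) -> frozenset[str]:
    """Union over contrasts of genes called up or down."""
    if not deg_tables:
        raise ValueError("need at least one DEG table")
    panel: set[str] = set()
    for table in deg_tables.values():
        panel |= set(table.index[table["status"].isin(["up", "down"])].astype(str))
    return frozenset(panel)


@dataclass(frozen=True)
class LinkageResult:
    leaf_order: tuple[str, ...]
    merge_steps: tuple[tuple[int, int, float], ...]
    gene_panel: tuple[str, ...]
    linkage_matrix: np.ndarray
    labels: tuple[str, ...]

    def to_json_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "leaf_order": list(self.leaf_order),
            "merge_steps": [
                {"cluster_a": a, "cluster_b": b, "height": h}
                for a, b, h in self.merge_steps
            ],
            "n_panel_genes": len(self.gene_panel),
        }


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    return np.where(sd > 0, z, 0.0)  # constant rows carry no signal


def cluster_strains(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    panel,
    distance: str = "euclidean",
    linkage: str = "complete",
    row_scale: str = "zscore",
    strains: Sequence[str] | None = None,
    collapse: str = "mean",
) -> LinkageResult:
    """Agglomerative clustering of strains over a dysregulated-gene panel.

    ``collapse="mean"`` clusters one column per strain (replicates averaged);
    ``collapse="replicates"`` keeps one column per sample.  ``row_scale`` is
    ``"zscore"`` or ``"none"``.  Deterministic for fixed inputs.
    """
    panel = sorted(set(map(str, panel)))
    if not panel:
        raise ValueError("gene panel is empty")
    if collapse == "mean":
        profiles = mean_expression(matrix, sheet)
    elif collapse == "replicates":
        profiles = matrix.values
    else:
        raise ValueError(f"unknown collapse mode {collapse!r}")
    if strains is not None:
        profiles = profiles[list(strains)]
    if profiles.shape[1] < 3:
        raise ValueError("clustering needs at least 3 strains/columns")
    missing = [g for g in panel if g not in profiles.index]
    if missing:
        raise ValueError(f"{len(missing)} panel genes missing from the matrix")
    x = np.log2(profiles.loc[panel].to_numpy(dtype=float) + 1.0)
    if row_scale == "zscore":
        x = _zscore_rows(x)
    elif row_scale != "none":
        raise ValueError(f"unknown row_scale {row_scale!r}")
    labels = tuple(profiles.columns)
    z = hierarchy.linkage(pdist(x.T, metric=distance), method=linkage)
    leaves = hierarchy.leaves_list(z)
    merge_steps = tuple((int(a), int(b), float(h)) for a, b, h, _ in z)
    return LinkageResult(
        leaf_order=tuple(labels[i] for i in leaves),
        merge_steps=merge_steps,
        gene_panel=tuple(panel),
        linkage_matrix=z,
        labels=labels,
    )
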