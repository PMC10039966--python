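"""Cross-strain set analysis: DEG overlaps, compensated genes, cis/trans
splits of co-regulated genes, and hypergeometric over-representation."""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dosage import CisTransPartition
from .io import GeneSetCollection

__all__ = [
    "OverlapResult",
    "overlap",
    "compensated_genes",
    "split_cis_trans",
    "CisTransSplit",
    "enrich",
]


@dataclass(frozen=True)
class OverlapResult:
    """Exact Venn-region counts for 2–4 labeled gene sets.

    ``region_counts`` maps each non-empty label combination (a tuple in input
    order) to the number of genes belonging to exactly those sets.
    """

    labels: tuple[str, ...]
    region_counts: dict[tuple[str, ...], int]
    pairwise: dict[tuple[str, str], int]

    def region(self, *labels: str) -> int:
        return self.region_counts[tuple(labels)]

    def to_json_dict(self) -> dict[str, int]:
        return {"&".join(k): v for k, v in self.region_counts.items()}


def overlap(sets: Mapping[str, Iterable[str]] | Iterable[tuple[str, Iterable[str]]]) -> OverlapResult:
    """Venn decomposition of 2 to 4 labeled gene sets."""
    items = list(sets.items()) if isinstance(sets, Mapping) else list(sets)
    labels = [l for l, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate set labels: {labels}")
    if not 2 <= len(labels) <= 4:
        raise ValueError(f"overlap supports 2-4 sets, got {len(labels)}")
    as_sets = {l: frozenset(map(str, g)) for l, g in items}
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = frozenset.intersection(*(as_sets[l] for l in combo))
            outside = frozenset().union(*(as_sets[l] for l in labels if l not in combo))
            regions[combo] = len(inside - outside)
    pairwise = {
        (a, b): len(as_sets[a] & as_sets[b])
        for a, b in itertools.combinations(labels, 2)
    }
    return OverlapResult(tuple(labels), regions, pairwise)


def compensated_genes(
    deg: pd.DataFrame,
    partition: CisTransPartition,
    p_threshold: float = 0.05,
    scope: str = "cis",
) -> frozenset[str]:
    """Genes whose expression the extra chromosome left statistically
    unchanged: expressed in both strains with p ≥ ``p_threshold``.

    By default only cis genes qualify (compensation of the extra chromosome
    is the biological question); ``scope="all"`` widens to every annotated-
    or-not expressed gene in the contrast.
    """
    if scope not in {"cis", "all"}:
        raise ValueError(f"scope must be 'cis' or 'all', got {scope!r}")
    sub = deg[(deg["status"] != "unexpressed") & (deg["p_value"] >= p_threshold)]
    genes = frozenset(sub.index.astype(str))
    if scope == "cis":
        genes &= partition.cis_genes
    return genes


class CisTransSplit(NamedTuple):
    cis: frozenset[str]
    trans: frozenset[str]
    unannotated: frozenset[str]


def split_cis_trans(genes: Iterable[str], partition: CisTransPartition) -> CisTransSplit:
    """Split a gene set by the strain's cis/trans partition; genes missing
    from the annotation are reported separately."""
    g = frozenset(map(str, genes))
    cis = g & partition.cis_genes
    trans = g & partition.trans_genes
    return CisTransSplit(cis, trans, g - cis - trans)


def enrich(
    query: Iterable[str],
    universe: Iterable[str],
    gene_sets: GeneSetCollection,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in the query set.

    For a term covering K of the N universe genes and a query of n genes
    containing k term members, the p-value is the upper tail
    P(X ≥ k) with X ~ Hypergeometric(N, K, n); q-values are BH-adjusted
    across terms and a term is significant when q < ``fdr``.
    """
    universe = frozenset(map(str, universe))
    query = frozenset(map(str, query))
    if not universe or not query:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError(f"{len(query - universe)} query genes are outside the universe")
    N, n = len(universe), len(query)
    rows = []
    for term, genes in gene_sets.items():
        term_genes = genes & universe
        K = len(term_genes)
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_value"])
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["significant"] = table["q_value"] < fdr
        table = table.sort_values(["p_value", "term"]).reset_index(drop=True)
    return table
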