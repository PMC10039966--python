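"""Cis/trans partitioning and expression-ratio distributions.

The core analysis: genes are split into *cis* (on a strain's extra
chromosome) and *trans* (all other annotated genes); aneuploid/diploid
expression ratios over genes expressed (FPKM > 0) in both strains are binned
in 0.05 increments; and the modal bin is classified against the canonical
demarcations — 1.50 (dosage effect), 1.00 (dosage compensation) and 0.67
(inverse trans response).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneAnnotation, GeneSetCollection, Karyotype, normalize_chromosome

__all__ = [
    "CisTransPartition",
    "RatioDistribution",
    "PeakCall",
    "DEMARCATIONS",
    "partition_cis_trans",
    "ratio_distribution",
    "peak_call",
    "group_distributions",
    "extreme_fraction",
]

#: Canonical ratio demarcations drawn as vertical guides on ratio maps.
DEMARCATIONS = {"inverse": 0.67, "compensation": 1.00, "dosage": 1.50}


@dataclass(frozen=True)
class CisTransPartition:
    strain_id: str
    cis_genes: frozenset[str]
    trans_genes: frozenset[str]


def partition_cis_trans(
    annotation: GeneAnnotation,
    karyotype: Karyotype,
    reference_extra: set[str] | None = None,
) -> CisTransPartition:
    """Split annotated genes into cis (on the extra chromosomes) and trans.

    For a euploid strain, ``reference_extra`` names the formerly extra
    chromosome(s) so its genes can still be analysed as the "cis" panel
    (the karyotypically normal offspring of a trisomic).  Supplying
    ``reference_extra`` for a strain that already has extra chromosomes is
    ambiguous and raises.
    """
    extra = karyotype.extra_chromosomes
    if reference_extra is not None:
        if extra:
            raise ValueError(
                f"strain {karyotype.strain_id!r} already has extra chromosomes "
                f"{sorted(extra)}; reference_extra is ambiguous"
            )
        extra = frozenset(normalize_chromosome(c) for c in reference_extra)
    cis = frozenset(g for g, c in annotation.items() if c in extra)
    trans = frozenset(annotation.genes) - cis
    return CisTransPartition(karyotype.strain_id, cis, trans)


@dataclass
class RatioDistribution:
    """Histogram of case/control expression ratios for a gene subset.

    Bins are half-open ``[edge, edge + bin_width)`` anchored at 0; ratios at
    or above ``cap`` are pooled into ``overflow_count``.  The raw per-gene
    ratios are retained so that exact quantiles and demarcation fractions do
    not depend on the binning.
    """

    subset_label: str
    bin_width: float
    bin_edges: np.ndarray
    counts: np.ndarray
    n_genes: int
    overflow_count: int
    ratios: pd.Series
    demarcations: dict[str, float] = field(default_factory=lambda: dict(DEMARCATIONS))

    @property
    def is_empty(self) -> bool:
        return self.n_genes == 0

    @property
    def midpoints(self) -> np.ndarray:
        return self.bin_edges[:-1] + self.bin_width / 2.0

    @property
    def frequencies(self) -> np.ndarray:
        """Counts normalized to proportions of included genes."""
        if self.n_genes == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.n_genes

    def median(self) -> float:
        if self.is_empty:
            raise ValueError("empty ratio distribution has no median")
        return float(self.ratios.median())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset_label": self.subset_label,
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "count": self.counts,
                "frequency": self.frequencies,
            }
        )


def _bin_index(ratios: np.ndarray, bin_width: float) -> np.ndarray:
    # floor(r / w) with a guard so that ratios representable as exact bin
    # edges (e.g. 1.5 / 0.05) land in the bin they open rather than one below.
    return np.floor(np.round(ratios / bin_width, 9)).astype(int)


def ratio_distribution(
    case_means: pd.Series,
    ctrl_means: pd.Series,
    subset,
    bin_width: float = 0.05,
    cap: float = 3.0,
    subset_label: str = "subset",
    allow_empty: bool = False,
) -> RatioDistribution:
    """Bin case/control mean-expression ratios for ``subset`` genes.

    Only genes expressed in both strains (mean > 0 on each side) enter the
    distribution; zero-expression genes are silently excluded, so a ratio is
    always well defined.
    """
    if bin_width <= 0 or cap <= 0:
        raise ValueError("bin_width and cap must be positive")
    genes = pd.Index(sorted(set(subset))).intersection(case_means.index)
    cm = case_means.reindex(genes)
    km = ctrl_means.reindex(genes)
    keep = (cm > 0) & (km > 0)
    ratios = (cm[keep] / km[keep]).sort_index()

    n_bins = int(round(cap / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    if len(ratios) == 0:
        if not allow_empty:
            raise ValueError(
                f"subset {subset_label!r} has no genes expressed in both strains"
            )
        return RatioDistribution(
            subset_label, bin_width, edges, np.zeros(n_bins, dtype=int), 0, 0, ratios
        )
    idx = _bin_index(ratios.to_numpy(), bin_width)
    overflow = int((idx >= n_bins).sum())
    counts = np.bincount(idx[idx < n_bins], minlength=n_bins).astype(int)
    return RatioDistribution(
        subset_label, bin_width, edges, counts, int(len(ratios)), overflow, ratios
    )


@dataclass(frozen=True)
class PeakCall:
    """Location and interpretation of a ratio distribution's main peak."""

    modal_midpoint: float
    classification: str
    tolerance: float


def _classify_peak(m: float, tol: float) -> str:
    if abs(m - DEMARCATIONS["dosage"]) <= tol:
        return "dosage_effect"
    if abs(m - DEMARCATIONS["compensation"]) <= tol:
        return "compensation"
    if abs(m - 2.0 / 3.0) <= tol:
        return "inverse"
    if DEMARCATIONS["compensation"] + tol < m < DEMARCATIONS["dosage"] - tol:
        return "intermediate"
    return "other"


def peak_call(
    dist: RatioDistribution, tolerance: float = 0.05, method: str = "mode"
) -> PeakCall:
    """Locate the distribution's main peak and classify it.

    ``method="mode"`` takes the midpoint of the highest-count bin (ties
    broken toward the lower ratio); ``method="kde"`` takes the argmax of a
    Gaussian kernel density (bandwidth = one bin width) over the raw ratios,
    useful when the histogram is flat.  Classification: dosage_effect at
    1.50 ± tolerance, compensation at 1.00 ± tolerance, inverse at
    2/3 ± tolerance, intermediate strictly between, otherwise other.
    """
    if dist.n_genes < 1:
        raise ValueError("peak_call requires a non-empty distribution")
    if method == "mode":
        if dist.counts.sum() == 0:
            raise ValueError("all in-range bin counts are zero; no peak to call")
        modal = float(dist.midpoints[int(np.argmax(dist.counts))])
    elif method == "kde":
        r = dist.ratios.to_numpy()
        if len(r) < 2 or np.ptp(r) == 0:
            modal = float(r[0])
        else:
            kde = stats.gaussian_kde(r, bw_method=dist.bin_width / r.std(ddof=1))
            grid = np.arange(dist.bin_width / 2, dist.bin_edges[-1], dist.bin_width / 10)
            modal = float(grid[int(np.argmax(kde(grid)))])
    else:
        raise ValueError(f"unknown peak method {method!r}")
    return PeakCall(modal, _classify_peak(modal, tolerance), tolerance)


def group_distributions(
    case_means: pd.Series,
    ctrl_means: pd.Series,
    gene_sets: GeneSetCollection,
    bin_width: float = 0.05,
    cap: float = 3.0,
) -> dict[str, RatioDistribution]:
    """One ratio distribution per functional group in the collection.

    A group with no genes expressed in both strains yields an empty
    distribution (``is_empty``) rather than an error.
    """
    return {
        name: ratio_distribution(
            case_means, ctrl_means, genes, bin_width, cap,
            subset_label=name, allow_empty=True,
        )
        for name, genes in gene_sets.items()
    }


def extreme_fraction(dist: RatioDistribution) -> dict[str, float]:
    """Fractions of included genes below 0.67, within [0.67, 1.50], and
    above 1.50 (overflow genes count as above).  Cutoffs are the printed
    demarcations, so an exact 2/3 ratio falls fractionally below 0.67."""
    if dist.n_genes < 1:
        raise ValueError("extreme_fraction requires a non-empty distribution")
    r = dist.ratios.to_numpy()
    lo, hi = DEMARCATIONS["inverse"], DEMARCATIONS["dosage"]
    below = float((r < lo).mean())
    above = float((r > hi).mean())
    return {
        "below_0.67": below,
        "within_0.67_1.50": float(1.0 - below - above),
        "above_1.50": above,
    }
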