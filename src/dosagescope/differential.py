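"""Replicate QC, mean expression, DEG calling and FPKM-stratified responses.

A gene is a DEG when its aneuploid/diploid fold change is at least 1.50
(symmetric: down means ratio ≤ 2/3) and its p-value is at most 0.05.  The
default p-value is a two-sided Welch t-test on log2(FPKM + 1) across
replicates; an ``external`` mode accepts any per-gene p-value table (e.g.
from a count-based DE tool) so the thresholds can be applied to someone
else's test.  Raw p-values gate DEG status; BH-adjusted q-values are
reported alongside for transparency but are not used for the call.
"""

from __future__ import annotations

import decimal
import itertools
import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, SampleSheet

__all__ = [
    "replicate_correlation",
    "mean_expression",
    "call_degs",
    "stratify",
    "stratum_summary",
    "stratum_logfc_test",
    "round_half_up",
]

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "ns"
STATUS_UNEXPRESSED = "unexpressed"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention behind printed percentages,
    where e.g. 63.925 rounds to 63.93 rather than banker's 63.92)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def replicate_correlation(
    matrix: ExpressionMatrix, sheet: SampleSheet, strain_id: str
) -> dict[tuple[str, str], float]:
    """Pearson correlation over genes for every replicate pair of a strain."""
    samples = sheet.samples_for(strain_id)
    if len(samples) < 2:
        raise ValueError(f"strain {strain_id!r} has fewer than 2 replicates")
    out = {}
    for a, b in itertools.combinations(samples, 2):
        x = matrix.values[a].to_numpy()
        y = matrix.values[b].to_numpy()
        out[(a, b)] = float(stats.pearsonr(x, y).statistic)
    return out


def mean_expression(matrix: ExpressionMatrix, sheet: SampleSheet) -> pd.DataFrame:
    """Per-gene arithmetic mean FPKM over each strain's replicates
    (genes × strains)."""
    cols = {s: matrix.values[sheet.samples_for(s)].mean(axis=1) for s in sheet.strains}
    return pd.DataFrame(cols, index=matrix.values.index)


def _welch_log_pvalues(case: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    """Two-sided Welch t on log2(FPKM+1) per gene.  Genes where both groups
    have zero within-group variance have an undefined statistic; their p is
    reported as 1.0 (no evidence against the null without variance)."""
    lx, ly = np.log2(case + 1.0), np.log2(ctrl + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(lx, ly, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (lx.var(axis=1, ddof=0) == 0) & (ly.var(axis=1, ddof=0) == 0)
    p = np.where(degenerate | ~np.isfinite(p), 1.0, p)
    return p


def call_degs(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    case: str,
    ctrl: str,
    fold_threshold: float = 1.5,
    p_threshold: float = 0.05,
    method: str = "welch_log",
    p_values: pd.Series | Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Call DEGs for one aneuploid-vs-diploid contrast.

    Returns a table indexed by gene id with columns ``mean_case``,
    ``mean_ctrl``, ``ratio``, ``log2fc``, ``p_value``, ``q_value`` and
    ``status`` (up / down / ns / unexpressed).  The ratio is the case/control
    mean FPKM; thresholds are inclusive (ratio = 1.50 with p = 0.05 is a DEG).
    """
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    case_cols = sheet.samples_for(case)
    ctrl_cols = sheet.samples_for(ctrl)
    case_vals = matrix.values[case_cols].to_numpy()
    ctrl_vals = matrix.values[ctrl_cols].to_numpy()
    mean_case = case_vals.mean(axis=1)
    mean_ctrl = ctrl_vals.mean(axis=1)
    expressed = (mean_case > 0) & (mean_ctrl > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expressed, mean_case / mean_ctrl, np.nan)
        log2fc = np.log2(ratio)

    if method == "welch_log":
        p = _welch_log_pvalues(case_vals, ctrl_vals)
    elif method == "external":
        if p_values is None:
            raise ValueError("method='external' requires a per-gene p-value table")
        p = pd.Series(p_values).reindex(matrix.values.index).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown DE method {method!r}")
    p = np.where(expressed, p, np.nan)

    q = np.full_like(p, np.nan)
    defined = np.isfinite(p)
    if defined.any():
        q[defined] = multipletests(p[defined], method="fdr_bh")[1]

    status = np.full(len(mean_case), STATUS_NS, dtype=object)
    sig = defined & (p <= p_threshold)
    status[sig & (ratio >= fold_threshold)] = STATUS_UP
    status[sig & (ratio <= 1.0 / fold_threshold)] = STATUS_DOWN
    status[~expressed] = STATUS_UNEXPRESSED

    return pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_ctrl": mean_ctrl,
            "ratio": ratio,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "status": status,
        },
        index=matrix.values.index,
    )


def stratify(
    diploid_means: pd.Series, boundaries: tuple[float, float] = (10.0, 100.0)
) -> pd.Series:
    """Assign expressed genes to FPKM strata on the diploid mean:
    low 0 < FPKM ≤ 10, medium 10 < FPKM ≤ 100, high FPKM > 100.
    Genes with mean 0 are unexpressed and excluded from the result."""
    lo, hi = boundaries
    if not 0 < lo < hi:
        raise ValueError("strata boundaries must satisfy 0 < low < high")
    m = diploid_means[diploid_means > 0]
    labels = np.where(m <= lo, "low", np.where(m <= hi, "medium", "high"))
    return pd.Series(labels, index=m.index, name="stratum")


def stratum_summary(deg: pd.DataFrame, strata: pd.Series) -> pd.DataFrame:
    """Per-stratum DEG counts and percentages (rounded half-up, 2 decimals).

    Percentages are NaN for a stratum with no DEGs.
    """
    rows = []
    for stratum in ("low", "medium", "high"):
        genes = strata.index[strata == stratum]
        sub = deg.loc[deg.index.intersection(genes)]
        sub = sub[sub["status"] != STATUS_UNEXPRESSED]
        n_expressed = len(sub)
        n_up = int((sub["status"] == STATUS_UP).sum())
        n_down = int((sub["status"] == STATUS_DOWN).sum())
        n_deg = n_up + n_down
        rows.append(
            {
                "stratum": stratum,
                "n_expressed": n_expressed,
                "n_deg": n_deg,
                "n_up": n_up,
                "n_down": n_down,
                "pct_deg": round_half_up(100.0 * n_deg / n_expressed) if n_expressed else np.nan,
                "pct_up_of_deg": round_half_up(100.0 * n_up / n_deg) if n_deg else np.nan,
                "pct_down_of_deg": round_half_up(100.0 * n_down / n_deg) if n_deg else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


def stratum_logfc_test(
    deg: pd.DataFrame,
    strata: pd.Series,
    stratum_a: str,
    stratum_b: str,
    exact_max_n: int = 20,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test comparing the log2 fold-change
    distributions of two FPKM strata.  Exact null distribution when the
    combined sample size is at most ``exact_max_n``, otherwise the normal
    approximation with continuity correction."""
    def _values(stratum: str) -> np.ndarray:
        genes = strata.index[strata == stratum]
        v = deg.loc[deg.index.intersection(genes), "log2fc"].to_numpy(dtype=float)
        return v[np.isfinite(v)]

    a, b = _values(stratum_a), _values(stratum_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError(
            f"stratum comparison needs expressed genes with defined log2fc in "
            f"both {stratum_a!r} (n={len(a)}) and {stratum_b!r} (n={len(b)})"
        )
    method = "exact" if len(a) + len(b) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
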