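"""DEG calling, replicate QC, FPKM stratification and stratified statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dosagescope.differential import (
    call_degs,
    mean_expression,
    replicate_correlation,
    round_half_up,
    stratify,
    stratum_logfc_test,
    stratum_summary,
)

from .conftest import make_matrix, make_sheet


class TestReplicateCorrelation:
    def test_identical_replicates_r_one(self):
        sheet = make_sheet({"A": 2})
        m = make_matrix({"A_r1": [1.0, 2, 3, 4], "A_r2": [1.0, 2, 3, 4]})
        assert replicate_correlation(m, sheet, "A")[("A_r1", "A_r2")] == pytest.approx(1.0)

    def test_exact_scaling_r_one(self):
        sheet = make_sheet({"A": 2})
        m = make_matrix({"A_r1": [1.0, 2, 3], "A_r2": [2.0, 4, 6]})
        assert replicate_correlation(m, sheet, "A")[("A_r1", "A_r2")] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        sheet = make_sheet({"A": 2})
        m = make_matrix({"A_r1": [1.0, 2, 3], "A_r2": [3.0, 2, 1]})
        assert replicate_correlation(m, sheet, "A")[("A_r1", "A_r2")] == pytest.approx(-1.0)

    def test_single_replicate_rejected(self):
        sheet = make_sheet({"A": 1})
        m = make_matrix({"A_r1": [1.0, 2]})
        with pytest.raises(ValueError, match="fewer than 2"):
            replicate_correlation(m, sheet, "A")


class TestMeanExpression:
    @pytest.mark.parametrize("reps,expected", [((4.0, 6.0), 5.0), ((0.0, 0.0), 0.0)])
    def test_two_replicates(self, reps, expected):
        sheet = make_sheet({"A": 2})
        m = make_matrix({"A_r1": [reps[0]], "A_r2": [reps[1]]})
        assert mean_expression(m, sheet).loc["g1", "A"] == expected

    def test_single_replicate_degenerate_mean(self):
        sheet = make_sheet({"A": 1})
        m = make_matrix({"A_r1": [7.0]})
        assert mean_expression(m, sheet).loc["g1", "A"] == 7.0


def _external_contrast(mean_case, mean_ctrl, p):
    """Matrix with constant replicates so strain means are exact; the
    external p-value path carries the chosen p."""
    sheet = make_sheet({"C": 2, "K": 2})
    m = make_matrix({
        "C_r1": [mean_case], "C_r2": [mean_case],
        "K_r1": [mean_ctrl], "K_r2": [mean_ctrl],
    })
    p_table = pd.Series({"g1": p})
    return call_degs(m, sheet, "C", "K", method="external", p_values=p_table)


class TestCallDegs:
    @pytest.mark.parametrize(
        "mc,mk,p,expected",
        [
            (15.0, 10.0, 0.01, "up"),      # ratio exactly 1.50, inclusive threshold
            (14.9, 10.0, 0.001, "ns"),     # ratio 1.49 just below
            (15.0, 10.0, 0.06, "ns"),      # p just above
            (15.0, 10.0, 0.05, "up"),      # p boundary inclusive
            (10.0, 15.0, 0.01, "down"),    # ratio exactly 2/3
            (0.0, 10.0, 0.01, "unexpressed"),
            (10.0, 0.0, 0.01, "unexpressed"),
        ],
    )
    def test_threshold_boundaries(self, mc, mk, p, expected):
        deg = _external_contrast(mc, mk, p)
        assert deg.loc["g1", "status"] == expected

    def test_status_partition_is_exhaustive(self, two_strain_data):
        matrix, sheet = two_strain_data
        deg = call_degs(matrix, sheet, "TRI", "WT")
        counts = deg["status"].value_counts()
        assert counts.sum() == len(matrix.gene_ids)
        assert set(counts.index) <= {"up", "down", "ns", "unexpressed"}

    def test_deg_count_monotone_in_thresholds(self):
        rng = np.random.default_rng(0)
        sheet = make_sheet({"C": 3, "K": 3})
        m = make_matrix({s: rng.lognormal(2, 1, 300) for s in sheet.sample_ids})
        def n_deg(fold, p):
            deg = call_degs(m, sheet, "C", "K", fold_threshold=fold, p_threshold=p)
            return int(deg["status"].isin(["up", "down"]).sum())
        for f1, f2 in [(1.2, 1.5), (1.5, 2.0)]:
            assert n_deg(f1, 0.2) >= n_deg(f2, 0.2)
        for p1, p2 in [(0.2, 0.05), (0.05, 0.01)]:
            assert n_deg(1.2, p1) >= n_deg(1.2, p2)

    def test_welch_matches_closed_form_on_random_fixtures(self):
        """Welch p on log2(FPKM+1) vs the textbook statistic with
        Welch-Satterthwaite degrees of freedom, to 1e-10."""
        rng = np.random.default_rng(1)
        sheet = make_sheet({"C": 3, "K": 4})
        m = make_matrix(
            {s: rng.lognormal(1.5, 1.0, 100) for s in sheet.sample_ids},
        )
        deg = call_degs(m, sheet, "C", "K")
        x = np.log2(m.values[sheet.samples_for("C")].to_numpy() + 1)
        y = np.log2(m.values[sheet.samples_for("K")].to_numpy() + 1)
        for i in range(100):
            vx, vy = x[i].var(ddof=1), y[i].var(ddof=1)
            nx, ny = len(x[i]), len(y[i])
            se2 = vx / nx + vy / ny
            t = (x[i].mean() - y[i].mean()) / math.sqrt(se2)
            df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
            p = 2 * sps.t.sf(abs(t), df)
            assert deg["p_value"].iloc[i] == pytest.approx(p, abs=1e-10)

    def test_zero_noise_gives_no_degs_without_variance(self):
        """Constant replicates carry no within-group variance: even a clean
        1.5-fold shift cannot reach significance under the Welch test."""
        deg = _external_contrast(15.0, 10.0, 0.01)  # external says significant
        assert deg.loc["g1", "status"] == "up"
        sheet = make_sheet({"C": 2, "K": 2})
        m = make_matrix({"C_r1": [15.0], "C_r2": [15.0], "K_r1": [10.0], "K_r2": [10.0]})
        welch = call_degs(m, sheet, "C", "K")
        assert welch.loc["g1", "p_value"] == 1.0
        assert welch.loc["g1", "status"] == "ns"

    def test_external_without_table_rejected(self, two_strain_data):
        matrix, sheet = two_strain_data
        with pytest.raises(ValueError, match="external"):
            call_degs(matrix, sheet, "TRI", "WT", method="external")


class TestStratify:
    @pytest.mark.parametrize(
        "mean,expected",
        [(0.5, "low"), (10.0, "low"), (10.01, "medium"), (100.0, "medium"),
         (100.01, "high"), (3000.0, "high")],
    )
    def test_half_open_boundaries(self, mean, expected):
        s = stratify(pd.Series({"g": mean}))
        assert s["g"] == expected

    def test_zero_mean_excluded(self):
        s = stratify(pd.Series({"g0": 0.0, "g1": 5.0}))
        assert "g0" not in s.index and s["g1"] == "low"


def _summary_from_counts(n_up, n_down, n_ns):
    """DEG table + strata holding exactly the given counts in one stratum."""
    statuses = ["up"] * n_up + ["down"] * n_down + ["ns"] * n_ns
    genes = [f"g{i}" for i in range(len(statuses))]
    deg = pd.DataFrame({"status": statuses, "p_value": 0.01, "log2fc": 0.0}, index=genes)
    strata = pd.Series("low", index=genes)
    return stratum_summary(deg, strata)


class TestStratumSummary:
    @pytest.mark.parametrize(
        "n_up,n_down,pct_up,pct_down",
        [
            (902, 509, 63.93, 36.07),   # 1,411 low-stratum DEGs
            (609, 732, 45.41, 54.59),   # 1,341 medium-stratum DEGs
            (109, 165, 39.78, 60.22),   # 274 high-stratum DEGs
        ],
    )
    def test_printed_percentages_reproduced(self, n_up, n_down, pct_up, pct_down):
        table = _summary_from_counts(n_up, n_down, 100)
        row = table.loc["low"]
        assert row["n_deg"] == n_up + n_down
        assert row["pct_up_of_deg"] == pct_up
        assert row["pct_down_of_deg"] == pct_down

    def test_up_down_percentages_complementary(self):
        row = _summary_from_counts(7, 13, 5).loc["low"]
        assert row["pct_up_of_deg"] + row["pct_down_of_deg"] == pytest.approx(100, abs=0.011)

    def test_empty_stratum_reports_nan(self):
        row = _summary_from_counts(0, 0, 10).loc["low"]
        assert row["n_deg"] == 0 and np.isnan(row["pct_up_of_deg"])

    def test_round_half_up_convention(self):
        assert round_half_up(63.925) == 63.93
        assert round_half_up(0.005) == 0.01


def _rank_sum_two_sided_exact(a, b):
    """Brute-force two-sided Wilcoxon rank-sum p: enumerate every assignment
    of the pooled ranks to group A and count statistics at least as extreme
    (by distance from the mean rank-sum) as observed."""
    pooled = sorted(a + b)
    ranks = {}
    for v in set(pooled):
        pos = [i + 1 for i, x in enumerate(pooled) if x == v]
        ranks[v] = sum(pos) / len(pos)
    obs = sum(ranks[v] for v in a)
    na = len(a)
    mean = na * (len(pooled) + 1) / 2
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        w = sum(ranks[pooled[i]] for i in combo)
        total += 1
        if abs(w - mean) >= abs(obs - mean) - 1e-12:
            hits += 1
    return hits / total


class TestStratumLogfcTest:
    def test_identical_multisets_p_one(self):
        genes = [f"g{i}" for i in range(6)]
        deg = pd.DataFrame({"log2fc": [1.0, 2, 3, 1, 2, 3], "status": "ns"}, index=genes)
        strata = pd.Series(["low"] * 3 + ["high"] * 3, index=genes)
        _, p = stratum_logfc_test(deg, strata, "low", "high")
        assert p == pytest.approx(1.0)

    def test_separated_groups_match_enumeration_oracle(self):
        genes = [f"g{i}" for i in range(6)]
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        deg = pd.DataFrame({"log2fc": a + b, "status": "ns"}, index=genes)
        strata = pd.Series(["low"] * 3 + ["high"] * 3, index=genes)
        _, p = stratum_logfc_test(deg, strata, "low", "high")
        oracle = _rank_sum_two_sided_exact(a, b)
        assert oracle == pytest.approx(0.1)
        assert p == pytest.approx(oracle)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_enumeration_on_random_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        a = list(np.round(rng.normal(0, 1, 4), 3))
        b = list(np.round(rng.normal(0.5, 1, 5), 3))
        genes = [f"g{i}" for i in range(9)]
        deg = pd.DataFrame({"log2fc": a + b, "status": "ns"}, index=genes)
        strata = pd.Series(["low"] * 4 + ["high"] * 5, index=genes)
        _, p = stratum_logfc_test(deg, strata, "low", "high")
        assert p == pytest.approx(_rank_sum_two_sided_exact(a, b), abs=1e-9)

    def test_empty_stratum_rejected(self):
        deg = pd.DataFrame({"log2fc": [1.0], "status": "ns"}, index=["g1"])
        strata = pd.Series(["low"], index=["g1"])
        with pytest.raises(ValueError, match="high"):
            stratum_logfc_test(deg, strata, "low", "high")
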