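import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triomix.annotation import GeneModel, RegionIndex
from triomix.diff_methylation import (
    adjust_pvalues,
    call_dms,
    dms_summary,
    feature_distribution,
    filter_coverage,
    fisher_exact_two_sided,
    lrt_two_group,
    profile_correlation,
    test_site as site_pvalue,
)
from triomix.io_formats import ConfigurationError, DataError, MethylationTable


def fisher_oracle(a, b, c, d):
    """Independent two-sided Fisher p: explicit lgamma hypergeometric sum."""
    r1, r2 = a + b, c + d
    n1 = a + c
    total = r1 + r2

    def logpmf(k):
        return (
            math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
            + math.lgamma(r2 + 1) - math.lgamma(n1 - k + 1) - math.lgamma(r2 - n1 + k + 1)
            - (math.lgamma(total + 1) - math.lgamma(n1 + 1) - math.lgamma(total - n1 + 1))
        )

    kmin = max(0, n1 - r2)
    kmax = min(r1, n1)
    p_obs = math.exp(logpmf(a))
    p = sum(
        math.exp(logpmf(k))
        for k in range(kmin, kmax + 1)
        if math.exp(logpmf(k)) <= p_obs * (1 + 1e-7)
    )
    return min(p, 1.0)


def bh_oracle(p):
    """Naive O(m^2) Benjamini-Hochberg step-up reference."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


class TestFisher:
    def test_hand_example_matches_enumeration_and_scipy(self):
        # group1 18/20 methylated vs group2 5/20
        p = fisher_exact_two_sided(18, 2, 5, 15)[0]
        assert p == pytest.approx(fisher_oracle(18, 2, 5, 15), rel=1e-9)
        assert p == pytest.approx(stats.fisher_exact([[18, 2], [5, 15]])[1], rel=1e-6)

    def test_symmetric_no_effect_table_gives_p_one(self):
        assert fisher_exact_two_sided(5, 5, 5, 5)[0] == pytest.approx(1.0)

    def test_random_tables_match_both_oracles(self):
        rng = np.random.default_rng(11)
        tables = rng.integers(0, 25, size=(300, 4))
        ours = fisher_exact_two_sided(*tables.T)
        for i, (a, b, c, d) in enumerate(tables):
            assert ours[i] == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9), (a, b, c, d)
            assert ours[i] == pytest.approx(
                stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-6
            ), (a, b, c, d)


class TestLRT:
    def test_identical_proportions_give_zero_statistic(self):
        g, p = lrt_two_group([10, 10], [20, 20], [5], [10])
        # same pooled proportion 0.5 in both groups
        assert g[0] == pytest.approx(0.0, abs=1e-10)
        assert p[0] == pytest.approx(1.0)

    def test_zero_coverage_group_untestable(self):
        _, p = lrt_two_group([0], [0], [5], [10])
        assert np.isnan(p[0])

    def test_matches_statsmodels_binomial_glm(self):
        # dual route: iteratively fitted logistic regression on the same data
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        for _ in range(20):
            m1, c1 = rng.integers(0, 30), rng.integers(30, 60)
            m2, c2 = rng.integers(0, 30), rng.integers(30, 60)
            g_ours, _ = lrt_two_group([m1], [c1], [m2], [c2])
            endog = np.array([[m1, c1 - m1], [m2, c2 - m2]], dtype=float)
            x = np.array([[1.0, 0.0], [1.0, 1.0]])
            full = sm.GLM(endog, x, family=sm.families.Binomial()).fit()
            null = sm.GLM(endog, x[:, :1], family=sm.families.Binomial()).fit()
            g_sm = null.deviance - full.deviance
            assert g_ours[0] == pytest.approx(g_sm, abs=1e-6)

    def test_test_site_dispatch(self):
        # 1 vs 1 samples -> Fisher; 2 vs 2 -> LRT
        p_fisher = site_pvalue([(18, 20), (5, 20)], ["A", "B"])
        assert p_fisher == pytest.approx(fisher_oracle(18, 2, 5, 15), rel=1e-9)
        p_lrt = site_pvalue([(5, 10), (5, 10), (5, 10), (5, 10)], ["A", "A", "B", "B"])
        assert p_lrt == pytest.approx(1.0)


class TestBH:
    def test_hand_stepup_example(self):
        # p*m/rank = [.04,.04,.04,.04] after monotone enforcement
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_identity_and_cap(self):
        assert adjust_pvalues([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(adjust_pvalues([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            adjust_pvalues([0.5, 1.2])

    def test_matches_naive_reference_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(adjust_pvalues(p), bh_oracle(p), atol=1e-12)


class TestFilterCoverage:
    def test_low_coverage_site_removed(self, toy_methylation):
        t = toy_methylation
        t.coverage.loc[1, "A1"] = 4
        out = filter_coverage(t, min_cov=10, max_pctile=100.0)
        assert out.n_sites == 3 and 200 not in out.sites["pos"].tolist()

    def test_all_removed_is_empty_not_error(self, toy_methylation):
        out = filter_coverage(toy_methylation, min_cov=1000)
        assert out.n_sites == 0

    def test_invalid_min_cov(self, toy_methylation):
        with pytest.raises(ValueError):
            filter_coverage(toy_methylation, min_cov=0)


class TestCallDms:
    def test_threshold_application(self, toy_methylation):
        res = call_dms(toy_methylation, "A", "B")
        by_pos = res.set_index("pos")
        # site 100: ~90% vs ~11% -> hyper; site 200: ~8% vs ~91% -> hypo
        assert by_pos.loc[100, "direction"] == "hyper"
        assert by_pos.loc[200, "direction"] == "hypo"
        assert by_pos.loc[300, "direction"] == "ns"
        assert by_pos.loc[100, "meth_diff"] == pytest.approx(
            by_pos.loc[100, "mean_pct_group1"] - by_pos.loc[100, "mean_pct_group2"]
        )

    def test_sub_cutoff_difference_is_ns_even_if_significant(self):
        # 80% vs 60% at huge coverage: q tiny but diff 20 < 25 pp
        n = 2000
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "strand": ["+"]})
        cov = pd.DataFrame({"A1": [n], "A2": [n], "B1": [n], "B2": [n]})
        meth = pd.DataFrame(
            {"A1": [int(n * 0.8)], "A2": [int(n * 0.8)], "B1": [int(n * 0.6)], "B2": [int(n * 0.6)]}
        )
        t = MethylationTable(sites=sites, coverage=cov, methylated=meth,
                             group_of={"A1": "A", "A2": "A", "B1": "B", "B2": "B"})
        res = call_dms(t, "A", "B")
        assert res["qvalue"].iloc[0] < 0.01
        assert res["direction"].iloc[0] == "ns"

    def test_missing_group_is_configuration_error(self, toy_methylation):
        with pytest.raises(ConfigurationError):
            call_dms(toy_methylation, "A", "C")

    def test_label_swap_negates_differences_and_swaps_directions(self, toy_methylation):
        ab = call_dms(toy_methylation, "A", "B")
        ba = call_dms(toy_methylation, "B", "A")
        np.testing.assert_allclose(ab["meth_diff"], -ba["meth_diff"])
        np.testing.assert_allclose(ab["pvalue"], ba["pvalue"])
        swap = {"hyper": "hypo", "hypo": "hyper", "ns": "ns"}
        assert [swap[d] for d in ab["direction"]] == list(ba["direction"])

    def test_summary_counts(self, toy_methylation):
        s = dms_summary(call_dms(toy_methylation, "A", "B"))
        assert s["n_dms"] == s["n_hyper"] + s["n_hypo"] == 2
        assert s["frac_hyper"] == pytest.approx(0.5)


class TestProfileCorrelation:
    def test_self_and_copy_correlation_unity(self, toy_methylation):
        t = toy_methylation
        t.coverage["B1"] = t.coverage["A1"]
        t.methylated["B1"] = t.methylated["A1"]
        c = profile_correlation(t)
        assert c.loc["A1", "A1"] == 1.0
        assert c.loc["A1", "B1"] == pytest.approx(1.0)

    def test_anticorrelated_toy_vectors(self):
        sites = pd.DataFrame({"chrom": ["c"] * 3, "pos": [1, 2, 3], "strand": ["+"] * 3})
        cov = pd.DataFrame({"s1": [10, 10, 10], "s2": [10, 10, 10]})
        meth = pd.DataFrame({"s1": [0, 5, 10], "s2": [10, 5, 0]})
        t = MethylationTable(sites=sites, coverage=cov, methylated=meth,
                             group_of={"s1": "A", "s2": "B"})
        assert profile_correlation(t).loc["s1", "s2"] == pytest.approx(-1.0)


class TestFeatureDistribution:
    def _dms(self, positions):
        return pd.DataFrame(
            {"chrom": ["chr1"] * len(positions), "pos": positions,
             "strand": ["+"] * len(positions),
             "direction": ["hyper"] * len(positions)}
        )

    def test_all_intergenic(self):
        idx = RegionIndex([GeneModel("g", "chr1", "+", 100, 200, exons=[(100, 200)])])
        d = feature_distribution(self._dms([5000, 6000]), idx)
        assert d["intergenic"] == 1.0 and d["promoter"] == 0.0

    def test_single_intron_site(self):
        g = GeneModel("g", "chr1", "+", 1000, 5000, exons=[(1000, 1499), (4500, 5000)])
        d = feature_distribution(self._dms([3000]), RegionIndex([g]))
        assert d["intron"] == 1.0 and d["exon"] == 0.0

    def test_matches_brute_force_on_random_genome(self):
        from conftest import brute_force_assign

        rng = np.random.default_rng(23)
        models = []
        cursor = 1000
        for i in range(30):
            start = cursor
            end = start + int(rng.integers(500, 2500))
            models.append(GeneModel(f"g{i}", "chr1", "+" if rng.random() < 0.5 else "-",
                                    start, end, exons=[(start, (start + end) // 2)]))
            cursor = end + int(rng.integers(100, 2000))
        idx = RegionIndex(models)
        positions = rng.integers(1, cursor + 2000, size=400).tolist()
        d = feature_distribution(self._dms(positions), idx)
        counts = {"promoter": 0, "exon": 0, "intron": 0, "intergenic": 0}
        for pos in positions:
            hits = brute_force_assign(models, 1500, "chr1", int(pos))
            if not hits:
                counts["intergenic"] += 1
                continue
            per_gene = {}
            for g, r in hits:
                per_gene.setdefault(g, set()).add(r)
            classes = set()
            for rs in per_gene.values():
                if "promoter" in rs:
                    classes.add("promoter")
                if "exon" in rs:
                    classes.add("exon")
                elif "intron" in rs:
                    classes.add("intron")
            for c in classes:
                counts[c] += 1
        for k in counts:
            assert d[k] == pytest.approx(counts[k] / len(positions))
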