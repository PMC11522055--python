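import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triomix.annotation import GeneModel, RegionIndex
from triomix.integration import (
    build_pairs,
    cross_comparison_sets,
    select_methylation_dependent,
    spearman,
    stratum_table,
)
from triomix.io_formats import ConfigurationError


def spearman_permutation_oracle(x, y):
    """Exhaustive rank-permutation p-value, coded independently."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def rho_of(a, b):
        return np.corrcoef(a, b)[0, 1]

    obs = rho_of(rx, ry)
    count = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(rx, np.array(perm))) >= abs(obs) - 1e-12:
            count += 1
    return obs, count / total


class TestSpearman:
    def test_perfect_inversion(self):
        rho, p = spearman([1, 2, 3], [3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_textbook_formula_untied_case(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d = (1,1,1,1) -> 1 - 24/60 = 0.6
        rho, _ = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_constant_vector_undefined(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_matches_permutation_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(4):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            rho, p = spearman(x, y)
            rho_ref, p_ref = spearman_permutation_oracle(x, y)
            assert rho == pytest.approx(rho_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_p_with_ties(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [4.0, 4.0, 2.0, 1.0, 1.0]
        rho, p = spearman(x, y)
        rho_ref, p_ref = spearman_permutation_oracle(x, y)
        assert rho == pytest.approx(rho_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho, p = spearman(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho, abs=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-9)


def _toy_setup():
    # gA: DMS in promoter; gB: DMS in body; one intergenic DMS
    gA = GeneModel("gA", "chr1", "+", 10000, 13999,
                   five_prime_utr=[(10000, 10199)], exons=[(10000, 10599)])
    gB = GeneModel("gB", "chr1", "+", 20000, 24999, exons=[(20000, 20599)])
    index = RegionIndex([gA, gB])
    dms = pd.DataFrame(
        {
            "chrom": ["chr1"] * 3,
            "pos": [9000, 22000, 50000],
            "strand": ["+"] * 3,
            "meth_diff": [40.0, -35.0, 30.0],
            "direction": ["hyper", "hypo", "hyper"],
        }
    )
    expr = pd.DataFrame(
        {
            "base_mean": [100.0, 50.0],
            "log2fc": [-2.0, -1.5],
            "padj": [0.001, 0.02],
            "tier": ["Q3", "Q2"],
        },
        index=["gA", "gB"],
    )
    norm = pd.DataFrame(
        {"A1": [120.0, 30.0], "A2": [110.0, 35.0], "B1": [420.0, 90.0], "B2": [400.0, 85.0]},
        index=["gA", "gB"],
    )
    return index, dms, expr, norm


class TestBuildPairs:
    def test_promoter_body_and_intergenic(self):
        index, dms, expr, norm = _toy_setup()
        pairs = build_pairs(dms, index, expr, norm, ["A1", "A2"], ["B1", "B2"])
        assert len(pairs) == 2
        pA = pairs[pairs["gene_id"] == "gA"].iloc[0]
        assert pA["region"] == "promoter"
        assert pA["expr_diff"] == pytest.approx(115.0 - 410.0)
        pB = pairs[pairs["gene_id"] == "gB"].iloc[0]
        assert pB["region"] == "gene_body" and pB["direction"] == "hypo"

    def test_gene_missing_expression_dropped(self):
        index, dms, expr, norm = _toy_setup()
        pairs = build_pairs(dms, index, expr.drop("gB"), norm, ["A1", "A2"], ["B1", "B2"])
        assert list(pairs["gene_id"]) == ["gA"]

    def test_overlapping_genes_give_two_pairs(self):
        g1 = GeneModel("g1", "chr1", "+", 1000, 20000, exons=[(1000, 1499)])
        g2 = GeneModel("g2", "chr1", "+", 10000, 12000, exons=[(10000, 12000)])
        index = RegionIndex([g1, g2])
        dms = pd.DataFrame({"chrom": ["chr1"], "pos": [9500], "strand": ["+"],
                            "meth_diff": [30.0], "direction": ["hyper"]})
        expr = pd.DataFrame({"base_mean": [1.0, 1.0], "log2fc": [0.0, 0.0],
                             "padj": [1.0, 1.0], "tier": ["Q2", "Q2"]},
                            index=["g1", "g2"])
        norm = pd.DataFrame({"s1": [1.0, 1.0], "s2": [1.0, 1.0]}, index=["g1", "g2"])
        pairs = build_pairs(dms, index, expr, norm, ["s1"], ["s2"])
        assert sorted(zip(pairs["gene_id"], pairs["region"])) == [
            ("g1", "gene_body"), ("g2", "promoter"),
        ]


class TestStratumTable:
    def _pairs(self, n=40, seed=0, region="promoter", direction="hyper", rho_sign=-1.0):
        rng = np.random.default_rng(seed)
        meth = rng.uniform(25, 60, size=n) * (1 if direction == "hyper" else -1)
        expr = rho_sign * meth * 10 + rng.normal(scale=20.0, size=n)
        return pd.DataFrame(
            {
                "chrom": "chr1", "pos": np.arange(n) + 1, "strand": "+",
                "gene_id": [f"g{i//2}" for i in range(n)],
                "region": region, "direction": direction,
                "meth_diff": meth, "expr_diff": expr,
                "gene_log2fc": -1.5, "gene_padj": 0.01, "tier": "Q3",
            }
        )

    def test_single_populated_stratum(self):
        pairs = self._pairs()
        tab = stratum_table(pairs)
        hot = tab[(tab["tier"] == "Q3") & (tab["region"] == "promoter")
                  & (tab["direction"] == "hyper")].iloc[0]
        assert hot["n_cpg"] == 40 and hot["n_genes"] == 20
        assert hot["spearman_rho"] < -0.5 and hot["spearman_p"] < 0.05
        empty = tab[(tab["tier"] == "Q1") & (tab["direction"] == "hypo")]
        assert (empty["n_cpg"] == 0).all() and empty["spearman_rho"].isna().all()

    def test_direction_split_counts_sum_to_total(self):
        pairs = pd.concat([self._pairs(direction="hyper"),
                           self._pairs(seed=1, direction="hypo")], ignore_index=True)
        tab = stratum_table(pairs).set_index(["tier", "region", "direction"])
        total = tab.loc[("all", "all", "hyper"), "n_cpg"] + tab.loc[("all", "all", "hypo"), "n_cpg"]
        assert total == len(pairs)

    def test_label_swap_maps_hyper_rows_to_hypo(self):
        pairs = self._pairs()
        swapped = pairs.copy()
        swapped["meth_diff"] *= -1
        swapped["expr_diff"] *= -1
        swapped["direction"] = "hypo"
        t1 = stratum_table(pairs).set_index(["tier", "region", "direction"])
        t2 = stratum_table(swapped).set_index(["tier", "region", "direction"])
        r1 = t1.loc[("Q3", "promoter", "hyper")]
        r2 = t2.loc[("Q3", "promoter", "hypo")]
        assert r1["n_cpg"] == r2["n_cpg"]
        assert r1["avg_meth_diff"] == pytest.approx(-r2["avg_meth_diff"])
        assert abs(r1["spearman_rho"]) == pytest.approx(abs(r2["spearman_rho"]))


class TestSelectMethylationDependent:
    def _pair(self, region, direction, lfc, padj=0.001, gene="g1"):
        return {
            "chrom": "chr1", "pos": 1, "strand": "+", "gene_id": gene,
            "region": region, "direction": direction, "meth_diff": 40.0,
            "expr_diff": -10.0, "gene_log2fc": lfc, "gene_padj": padj, "tier": "Q3",
        }

    def test_promoter_hyper_with_downregulation_is_hit(self):
        pairs = pd.DataFrame([self._pair("promoter", "hyper", -2.0)])
        out = select_methylation_dependent(pairs)
        assert list(out["promoter"]["gene_id"]) == ["g1"]
        assert out["promoter"]["label"].iloc[0] == "hypermeth"

    def test_promoter_hyper_with_upregulation_is_not(self):
        pairs = pd.DataFrame([self._pair("promoter", "hyper", +2.0)])
        assert select_methylation_dependent(pairs)["promoter"].empty

    def test_body_hyper_with_upregulation_is_body_hit(self):
        pairs = pd.DataFrame([self._pair("gene_body", "hyper", +2.0)])
        out = select_methylation_dependent(pairs)
        assert list(out["gene_body"]["gene_id"]) == ["g1"]

    def test_insignificant_gene_excluded(self):
        pairs = pd.DataFrame([
            self._pair("promoter", "hyper", -2.0, padj=0.2),
            self._pair("promoter", "hyper", -0.5, padj=0.001, gene="g2"),
        ])
        out = select_methylation_dependent(pairs)
        assert out["promoter"].empty

    def test_gene_counted_once_with_multiple_dms(self):
        pairs = pd.DataFrame([
            self._pair("promoter", "hyper", -2.0),
            self._pair("promoter", "hyper", -2.0),
        ])
        out = select_methylation_dependent(pairs)["promoter"]
        assert len(out) == 1 and out["n_dms"].iloc[0] == 2


class TestCrossComparison:
    def test_three_way_intersection_and_direction_labels(self):
        lists = {
            "AvsB": {"g1": "hypermeth", "g2": "hypermeth"},
            "AvsC": {"g1": "hypometh"},
            "BvsC": {"g1": "hypermeth", "g3": "hypometh"},
        }
        out = cross_comparison_sets(lists).set_index("gene_id")
        assert out.loc["g1", "n_comparisons"] == 3
        assert out.loc["g1", "pattern"] == "AvsB_hypermeth AvsC_hypometh BvsC_hypermeth"
        assert out.loc["g2", "membership"] == "AvsB"

    def test_disjoint_lists_all_singletons(self):
        lists = {"X": {"g1": "hypermeth"}, "Y": {"g2": "hypometh"}}
        out = cross_comparison_sets(lists)
        assert (out["n_comparisons"] == 1).all()

    def test_pattern_counts_match_brute_force(self):
        rng = np.random.default_rng(77)
        genes = [f"g{i}" for i in range(60)]
        lists = {
            name: {g: "hypermeth" for g in rng.choice(genes, size=25, replace=False)}
            for name in ("c1", "c2", "c3")
        }
        out = cross_comparison_sets(lists)
        for g in genes:
            expected = "&".join(c for c in sorted(lists) if g in lists[c])
            if expected:
                assert out.set_index("gene_id").loc[g, "membership"] == expected
            else:
                assert g not in set(out["gene_id"])

    def test_single_comparison_rejected(self):
        with pytest.raises(ConfigurationError):
            cross_comparison_sets({"only": {"g": "hypermeth"}})
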