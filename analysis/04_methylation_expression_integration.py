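#!/usr/bin/env python
"""Pair DMSs with host-gene expression and summarize by stratum.

Every called DMS is joined to the promoters/bodies it overlaps; pairs are
stratified by expression tier x region x methylation direction, each
stratum summarized by counts, mean differences, and the Spearman
correlation of (methylation difference, expression difference).  Genes
whose significant expression change matches the canonical sign rule
(promoter methylation represses; body methylation tracks) are selected
as methylation-dependent.
"""

from pathlib import Path

import pandas as pd

from triomix.annotation import RegionIndex, load_gene_models
from triomix.diff_expression import assign_tiers, normalized_counts, test_de
from triomix.diff_methylation import call_dms, filter_coverage
from triomix.integration import build_pairs, select_methylation_dependent, stratum_table
from triomix.io_formats import read_count_table, read_methylation_table

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "results" / "simulated_cohort"
OUTDIR = ROOT / "results" / "integration"


def main() -> None:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    sheet = pd.read_csv(COHORT / "sample_sheet.tsv", sep="\t")
    sample_sheet = dict(zip(sheet["sample"], sheet["group"]))
    meth = filter_coverage(
        read_methylation_table(COHORT / "methylation.tsv", sample_sheet), min_cov=10
    )
    counts = read_count_table(COHORT / "gene_counts.tsv", sample_sheet)
    index = RegionIndex(load_gene_models(COHORT / "annotation.gtf"))

    dms = call_dms(meth, "A", "B")
    expr = assign_tiers(test_de(counts, "A", "B"))
    norm = normalized_counts(counts)
    s1 = counts.samples_in_group("A")
    s2 = counts.samples_in_group("B")

    pairs = build_pairs(dms, index, expr, norm, s1, s2)
    pairs.to_csv(OUTDIR / "site_gene_pairs.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print(f"{len(pairs)} CpG-gene pairs from "
          f"{int((dms['direction'] != 'ns').sum())} DMSs")

    strata = stratum_table(pairs)
    strata.to_csv(OUTDIR / "stratum_table.tsv", sep="\t", index=False,
                  float_format="%.6g")
    show = strata[(strata["tier"] == "all") & (strata["region"] != "all")]
    for _, r in show.iterrows():
        rho = "NA" if pd.isna(r["spearman_rho"]) else f"{r['spearman_rho']:+.3f}"
        print(f"  {r['region']:>8} {r['direction']:>5}: n_cpg={r['n_cpg']:>3} "
              f"genes={r['n_genes']:>3} rho={rho}")

    dep = select_methylation_dependent(pairs, max_padj=0.05, min_abs_lfc=1.0)
    for cls, df in dep.items():
        df.to_csv(OUTDIR / f"meth_dependent_{cls}.tsv", sep="\t", index=False,
                  float_format="%.6g")
        print(f"methylation-dependent ({cls}): {len(df)} genes")


if __name__ == "__main__":
    main()
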