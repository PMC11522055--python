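#!/usr/bin/env python
"""Generate the simulated two-tissue cohort all downstream analyses consume.

Emulated design: two tissue groups (A vs B) of four animals each, ~30x
RRBS coverage with beta-binomial replicate noise, NB mRNA/miRNA counts,
40-pp planted differential CpGs, 4-fold planted expression changes,
promoter-methylation/expression anti-coupling, and one planted
methylation -> miRNA -> mRNA cascade.  Inputs land in
results/simulated_cohort/ in the pipeline's exchange dialects, alongside
the planted-truth tables.
"""

from pathlib import Path

from triomix.simulate import SimulationConfig, simulate_dataset, write_dataset

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "simulated_cohort"
SEED = 1


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    ds = simulate_dataset(cfg)
    write_dataset(ds, OUTDIR)
    print(f"wrote {OUTDIR}")
    print(f"  CpG sites:      {ds.methylation.n_sites}")
    print(f"  genes/miRNAs:   {len(ds.gene_counts.feature_ids)}/{len(ds.mirna_counts.feature_ids)}")
    print(f"  planted DMSs:   {len(ds.truth.dms)}")
    print(f"  planted DE:     {len(ds.truth.de_genes)} genes, {len(ds.truth.de_mirnas)} miRNAs")
    print(f"  coupled genes:  {len(ds.truth.coupled_genes)}")
    print(f"  cascades:       {len(ds.truth.cascades)} "
          f"({ds.truth.cascades['n_targets'].sum()} targets)")


if __name__ == "__main__":
    main()
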