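# triomix

Integrative differential analysis of RRBS DNA methylation, mRNA expression,
and miRNA expression between tissues — the kind of tri-omics design used to
ask how promoter methylation, gene-body methylation, and miRNA repression
jointly shape tissue-specific expression (e.g. heart / lung / liver panels
from a small cohort of animals).

The package is aimed at analysts who have per-CpG methylation call tables,
raw count matrices, and a GTF, and want a transparent, fully testable
re-implementation of the standard integration recipe rather than a chain of
web tools. Every statistical step is simple enough to verify against an
independent oracle, and a planted-truth simulator makes the whole pipeline
checkable end to end without any external data.

## What it computes

**Differential methylation.** Per CpG site, two tissue groups are compared
on (methylated, coverage) counts: a two-sided Fisher exact test on the
pooled 2×2 table when each group has one sample, otherwise a
likelihood-ratio test of the group effect in a binomial logistic regression
(closed form for a single two-level factor). p-values are Benjamini–Hochberg
adjusted; a site is a DMS when

&nbsp;&nbsp;&nbsp;&nbsp;|Δm| ≥ 25 percentage points and q < 0.01,

with Δm = mean %methylation(group 1) − mean %methylation(group 2); "hyper"
means hypermethylated in the first-named group.

**Differential expression.** A deliberately plain negative-binomial Wald
test: median-of-ratios size factors s_j, method-of-moments dispersion
α̂ = max(floor, (s² − μ)/μ²) from within-group pooled variances, moderated
log2 fold change log2((m̄₁+0.5)/(m̄₂+0.5)), delta-method standard error, BH
adjustment. A feature is DE when padj < 0.05 and |log2FC| ≥ 1. Genes are
tiered by quartiles of mean normalized expression: Q1 (low), Q2
(interquartile, medium), Q3 (high).

**Region model.** Promoter = TSS1500 (the 1,500 bp strictly upstream of the
TSS on the gene's strand) ∪ annotated 5′UTR; gene body = transcribed span
minus 5′UTR, partitioned into exon/intron; everything else intergenic.
Multi-transcript genes collapse to exon/UTR unions with the 5′-most TSS.

**Integration.** Each DMS is paired with every overlapping promoter/body;
pairs are stratified by expression tier × region × methylation direction,
and each stratum is summarized by counts, mean methylation difference (pp),
mean expression difference (normalized counts), and the Spearman correlation
of (Δmethylation, Δexpression) across the stratum's CpG–gene pairs (exact
permutation p-value for n ≤ 8). Methylation-dependent genes follow the
canonical sign rules: promoter methylation opposing a significant expression
change, gene-body methylation matching it. Gene lists from multiple
comparisons are partitioned by exact membership pattern.

**miRNA layer.** Targets come from a transparent 7mer-m8 seed match
(reverse complement of miRNA nt 2–8 in the 3′UTR) or a user-supplied map;
a miRNA–target pair is retained when sample-level Spearman r < −0.9 and the
target is DE. A regulatory chain links promoter DMSs of a miRNA gene to a
DE miRNA whose expression anti-correlates with its promoter methylation,
and onward to its negatively correlated DE targets.

**Simulator.** `triomix.simulate` generates a toy annotated chromosome,
beta-binomial methylomes (~30× coverage, precision 30), and NB count
matrices for a 4 vs 4 two-group design, with planted 40-pp DMSs, 4-fold
expression changes, promoter-methylation↔expression anti-coupling, and
planted cascades whose shared per-sample latent factor drives the
miRNA–target rank anti-correlation. Every planted effect is recorded in a
truth table.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
cohort and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_differential_methylation.py
python analysis/03_differential_expression.py
python analysis/04_methylation_expression_integration.py
python analysis/05_mirna_regulatory_chains.py
python analysis/06_planted_truth_evaluation.py
```

Output of a run (seed 1):

```
coverage filter: 558 -> 531 CpGs
DMSs: 70 of 531 tested (43 hyper / 27 hypo, 61.4% hypermethylated in A)
DMS feature distribution: promoter 37.1%, exon 17.1%, intron 38.6%, intergenic 7.1%
mrna: 60 features, size factors 0.898-1.134; 19 DE (12 up, 7 down in A)
...
chain mir1: log2FC -1.81, promoter-methylation vs expression r = -0.810 (p = 0.022),
  5 target links, target r range [-0.952, -0.714]
   promoter_coupled: sensitivity 100.0%  FDR 0.0%  (8 called / 8 planted)
             chains: sensitivity 100.0%  FDR 0.0%  (1 called / 1 planted)
```

Reading: of 531 testable CpGs, 70 pass the 25-pp / q<0.01 cutoffs, nearly
all of them planted (97% sensitivity, 3% FDR in the recovery report). The
planted cascade is reconstructed as one chain: a hypermethylated miRNA
promoter, the miRNA ~3.5-fold down, promoter methylation anti-correlated
with its expression, and five of six planted targets linked with negative
sample-level correlations.

The same pipeline runs from a single YAML config:

```sh
triomix run --config cfg.yaml        # real or simulated inputs
triomix simulate --seed 1 --out sim/ # just the dataset + truth tables
triomix evaluate --config cfg.yaml   # run + score against planted truth
```

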