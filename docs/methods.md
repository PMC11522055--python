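# Methods

## Scope and data model

The pipeline consumes per-CpG methylation call tables (chrom, 1-based
cytosine position, strand, per-sample coverage and methylated counts),
feature × sample raw count matrices for genes and miRNAs, and gene models
from GTF/GFF3. Upstream read processing (trimming, alignment, methylation
calling, miRNA discovery) is out of scope; the call/count tables are the
interface. CpG sites on opposite strands of a symmetric CpG are kept
distinct — no destranding — because merging is lossy and the convention is
explicit either way. All parsers are strict: a malformed row, a methylated
count exceeding coverage, or a duplicate site aborts the load with the
offending row named, rather than silently shrinking the data.

## Differential methylation

Sites are first coverage-filtered: every sample must have ≥ `min_cov`
(default 10×) and ≤ its own 99.9th-percentile coverage (a guard against
PCR-duplicated pile-ups). Both bounds are ordinary RRBS practice; they are
exposed as parameters.

The group test operates on per-group pooled totals. With one sample per
group (or `pool_replicates=true`) it is a two-sided Fisher exact test: the
p-value is the hypergeometric mass of all 2×2 tables with the observed
margins whose probability does not exceed the observed table's, with a
relative tie tolerance of 1e-7. The implementation is vectorized over sites
via the hypergeometric pmf on a padded support matrix; a test suite oracle
re-derives every p-value by explicit lgamma enumeration over all tables
with margins ≤ 40, and a subsample is cross-checked against
`scipy.stats.fisher_exact`.

With replicates the test is a likelihood-ratio test of the group effect in
a binomial logistic regression on (methylated, coverage). For a single
two-level factor the GLM maximum likelihood is attained exactly at the
coverage-pooled group proportions, so the deviance difference has a closed
form, G = 2(ℓ(p̂₁, p̂₂) − ℓ(p̂₀)), with p from χ²(1). This is computed
vectorized across all sites; equivalence with an iteratively fitted
`statsmodels` binomial GLM is asserted in the unit tests. A site where
either group has zero total coverage is untestable and excluded (reported,
not silently dropped).

Multiple testing uses Benjamini–Hochberg throughout (`statsmodels`
`multipletests` behind a thin validated wrapper; an O(m²)-style naive
step-up reference serves as the test oracle). A site is a DMS when
|Δm| ≥ 25 pp and q < 0.01, where Δm is the difference of unweighted
per-sample mean methylation percentages, group 1 − group 2. In a comparison
named "AvsB", "hyper" means hypermethylated in A. The 25-pp / q<0.01
defaults follow the strict threshold convention for site-level RRBS calls;
both are flags (`--min-diff`, `--max-q`), and q<0.05 is available where a
looser screen is wanted.

Pooling replicate counts makes the replicated test anticonservative under
between-replicate overdispersion; the planted-truth calibration shows the
joint difference+q criterion nonetheless keeps the realized false-call rate
under 1% at the simulated design (the |Δm| ≥ 25 arm does most of that
work). Site-level dispersion-corrected tests are a deliberate non-goal.

## Region model

Promoter = TSS1500 ∪ 5′UTR. TSS1500 is the 1,500 bp strictly upstream of
the TSS on the gene's strand — exclusive of the TSS base, which begins the
5′UTR when annotated, so the two never double-count. Gene body is the
transcribed span minus the 5′UTR (the 3′UTR stays inside the body); exons
intersected with the body and their complement partition it into
exon/intron. Multi-transcript genes collapse to gene level: exon and UTR
unions, one TSS at the 5′-most transcribed position. A CpG overlapping
several genes is assigned to all of them and contributes to each host
gene's statistics independently; dropping or nearest-TSS tie-breaking would
hide signal. CpG strand is ignored at assignment since regions are defined
by the gene's strand. Lookup uses an interval tree; a brute-force linear
scan over all gene intervals is the test oracle.

## Differential expression

One NB engine serves mRNA and miRNA tables. Size factors are
median-of-ratios against the per-feature geometric mean, computed over
features positive in every sample (falling back to each sample's positive
subset when none exists). Dispersion is a per-feature method-of-moments
estimate α̂ = max(10⁻⁸, (s² − μ)/μ²) with s² the df-weighted pooled
within-group variance of normalized counts and μ their grand mean. The test
is a Wald z on the moderated log2 fold change (pseudocount 0.5 on each
group mean) with a delta-method SE propagating Var(K) = μ + αμ² through the
group means; BH adjustment; DE at padj < 0.05 and |log2FC| ≥ 1.

No fold-change shrinkage and no outlier refitting: the estimator is meant
to be auditable line by line, and the acceptance checks are calibration
properties (null type-I control, planted recovery), not agreement with any
particular production tool. A unit test nevertheless cross-checks sign and
rough magnitude of a strong planted fold change against an independent
DESeq2-style fit (pydeseq2).

Expression tiers: features ranked by mean normalized count (ties broken by
feature id); with k = ⌊n/4⌋ the bottom k are Q1, the top k Q3, and the
middle the "medium" Q2 — i.e. medium is the interquartile half, since the
top and bottom quartiles are what the high/low classes name. Tiers are
computed per comparison by default.

## Methylation–expression integration

Pairs are (DMS × overlapping promoter-or-body of an expressed gene); each
pair carries Δm, the gene's expression difference of mean normalized counts
(group 1 − group 2, unlogged so magnitudes are interpretable), log2FC,
padj, and tier. The stratum table crosses {all, Q3, Q2, Q1} ×
{all, body, promoter} × {hyper, hypo}; per stratum it reports the number of
CpG–gene pairs, distinct genes, mean Δm, mean Δexpression, and the Spearman
correlation of (Δm, Δexpression) across the stratum's pairs with its
significance. The correlated quantities are per-pair differences — the
reading that makes one correlation per stratum row well-defined next to the
row's counts and mean differences; a sample-level per-gene alternative
would produce one correlation per gene, not per stratum. Empty strata emit
rows with zero counts; ρ needs ≥ 3 pairs. Spearman uses average ranks for
ties; its two-sided p-value is an exhaustive permutation enumeration for
n ≤ 8 (40,320 permutations, vectorized and cached — covering the 4 vs 4
study design) and the t-approximation with n−2 df above that. Normality
pre-testing is deliberately absent: the rank correlation is applied
unconditionally.

Methylation-dependent genes: promoter class = ≥ 1 promoter DMS whose
direction opposes a significant expression change (hyper→down, hypo→up;
padj < 0.05, |log2FC| ≥ 1); body class = ≥ 1 body DMS matching the change.
A gene counts once per class regardless of how many DMSs qualify (the DMSs
still count individually in the stratum table). Cross-comparison
partitioning maps every selected gene to its exact membership pattern with
per-comparison direction labels.

## miRNA layer

Target prediction is a canonical-seed stand-in: a (miRNA, gene) pair is
emitted when the reverse complement of the miRNA seed (nt 2–8, 7mer-m8)
occurs in the gene's 3′UTR given 5′→3′; U/T are normalized, other symbols
rejected. This replaces consensus web predictors on purpose — it is
deterministic, versionless, and transparent — and a user-supplied target
map TSV bypasses it entirely. Its target sets are not expected to match any
thermodynamic predictor's.

Retained miRNA–target pairs need sample-level Spearman r < −0.9 (the same
Spearman implementation as the integration layer, bit for bit) and a DE
target. Chains require: ≥ 1 DMS in the miRNA gene's promoter (TSS1500-only
when no UTR is annotated, the typical miRNA case), a DE miRNA, negative
Spearman between mean promoter-DMS methylation and miRNA expression across
samples, and ≥ 1 negatively correlated DE target. All negative target
correlations are reported with the r < −0.9 subset flagged, so the chain
report shows the full evidence while the hard cutoff stays visible.

## Simulator

The generator emulates the target study design: two tissue groups × 4
animals (a 4 vs 3 mode mirrors a dropped sample), ~30× NB-distributed
coverage, beta-binomial methylation with precision 30 (so the replicated
LRT path faces real overdispersion), log-normal expression baselines
(meanlog 4.5, sdlog 1), NB dispersion 0.02 (biological CV ≈ 14%, typical of
tissue replicates from a genetically homogeneous cohort), and a ±10% depth
factor per sample to exercise normalization.

Planted effects: promoter baselines ~10% methylation, bodies ~70%; DMSs
shift the between-group proportion by exactly ±40 pp (the baseline slides
so both groups stay inside (0.01, 0.99) and the difference is realized in
full); DE features shift by ±log2FC 2, split symmetrically across groups;
coupled genes get all promoter CpGs shifted together and an expression
shift of the opposite sign. Cascades plant a hypermethylated miRNA promoter
(group 1), the miRNA 4-fold down, and six targets 4-fold up.

Rank anti-coupling uses a shared per-sample latent factor: miRNA counts are
scaled by 2^(−λz_j), targets by 2^(+λz_j), and the miRNA promoter
methylation proportion moves with +z_j. The latent z takes standardized
normal scores within each group in random order — zero within-group mean,
so planted fold changes stay exact, with a stable spread that carries the
within-group ranking. λ (default 0.6) balances two opposing requirements
the design imposes jointly: large enough that planted miRNA–target pairs
reach Spearman r < −0.9 across 8 samples (median planted-pair r ≈ −0.96),
small enough that the extra within-group variance leaves the 4 vs 4 Wald
test able to call the 4-fold miRNA change (≈ 98% of runs). A Gaussian
latent is noticeably worse on both counts because its within-group gaps are
unstable.

What the simulator does **not** emulate: genomic sequence composition, read
-level error, CpG density structure, batch effects, correlated
methylation along the genome, or miRNA-family seed redundancy. Passing
tests therefore demonstrate the pipeline's statistical calibration and its
bookkeeping (coordinates, strands, joins), not performance on the noise
structure of any particular real dataset.

## Pipeline and determinism

`run_pipeline` is a pure function of (inputs, config, seed): fixed stage
order, all outputs sorted before writing, floats formatted to 6 significant
digits, manifests without timestamps — identical runs are byte-identical.
The manifest records the config hash, seed, package version, and per-stage
row counts. Any stage failure aborts with the comparison named.

Truth evaluation reports sensitivity and empirical FDR per planted class.
DMS sensitivity is computed over planted sites that survived coverage
filtering (the caller cannot recover a site it never saw); the unfiltered
planted total is reported alongside, and FDR counts every called
non-planted site.

## Problem sizes in the test suite

The statistical acceptance tests use: the exhaustive Fisher sweep over all
2×2 tables with margins ≤ 40 (~741k tables); 1,000 random BH vectors; full
permutation enumeration for Spearman at n ≤ 7; 500 null replicates of
~2,000 CpGs and 220 genes for calibration; 200 replicates each for planted
DMS/DEG recovery and integration recovery; 100 null replicates for the
chain analysis. The whole suite runs in a few minutes on one CPU; sizes
were chosen so each rate estimate has enough events to be stable at the
asserted thresholds.

## Known limitations

- The replicated methylation test pools counts within groups; replicate
  overdispersion is absorbed only by the difference threshold, not modeled.
- No differentially methylated *region* (tile) calling; sites only.
- The NB Wald test is unshrunk; very-low-count features rely on the
  pseudocount and the |log2FC| threshold for stability.
- The seed-match target map has the usual canonical-seed false
  positives/negatives; the r < −0.9 filter is what carries specificity.
- Multi-gene CpGs contribute to every host gene, so stratum rows are not
  independent across genes.
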