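"""Coupled tri-omics simulator with planted truth.

Generates a toy annotated chromosome, a beta-binomial RRBS methylome, and
NB-distributed mRNA/miRNA count matrices whose planted effects mirror the
study design the pipeline targets: two tissue groups of four animals,
~30x CpG coverage, differential sites shifted by 40 percentage points,
differentially expressed features shifted 4-fold, promoter methylation
anti-coupled to host-gene expression, and one or more regulatory cascades
(hypermethylated miRNA promoter -> miRNA down -> targets up) in which a
shared per-sample latent factor drives the methylation/miRNA/target rank
anti-correlations the r < -0.9 filter requires.

Every generated effect is recorded in a :class:`TruthTable`, and generation
is fully deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneModel, RegionIndex
from .io_formats import (
    CountTable,
    MethylationTable,
    write_count_table,
    write_methylation_table,
)

__all__ = ["SimulationConfig", "TruthTable", "SimulatedDataset", "simulate_dataset",
           "simulate_annotation", "simulate_methylome", "simulate_expression",
           "write_dataset"]

CHROM = "chrT"
SEED_ALPHABET = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-design parameters for the simulator.

    Defaults encode the emulated design: 4 vs 4 samples, 30x mean coverage,
    beta-binomial precision 30, 40-pp planted methylation shifts, 4-fold
    (log2fc 2) planted expression changes, and one planted cascade with six
    anti-coupled targets.
    """

    seed: int = 0
    n_genes: int = 60
    n_mirnas: int = 6
    n_cpg_per_gene: int = 8          # ~1/3 promoter, rest gene body
    n_intergenic_cpg: int = 60
    n_per_group: tuple[int, int] = (4, 4)
    group_labels: tuple[str, str] = ("A", "B")
    coverage_mean: float = 30.0
    coverage_size: float = 10.0      # NB shape of per-site coverage
    bb_precision: float = 30.0       # beta-binomial concentration
    dms_fraction: float = 0.10
    dms_shift_pp: float = 40.0
    de_fraction: float = 0.10
    de_log2fc: float = 2.0
    n_coupled_genes: int = 8
    promoter_coupling_strength: float = 2.0  # |log2fc| induced by coupled promoter shift
    n_cascades: int = 1
    n_targets_per_cascade: int = 6
    cascade_latent_strength: float = 0.6     # log2 units per latent s.d.
    cascade_meth_latent_pp: float = 8.0      # pp of promoter methylation per latent s.d.
    expr_meanlog: float = 4.5
    expr_sdlog: float = 1.0
    expr_dispersion: float = 0.02
    depth_sdlog: float = 0.1
    utr_seq_length: int = 300
    promoter_baseline: float = 0.10
    body_baseline: float = 0.70

    def __post_init__(self) -> None:
        for frac in (self.dms_fraction, self.de_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 < self.dms_shift_pp < 100.0:
            raise ValueError("dms_shift_pp must lie in (0, 100)")
        if min(self.n_genes, self.n_per_group[0], self.n_per_group[1]) < 1:
            raise ValueError("sizes must be >= 1")
        if self.n_cascades > 0 and self.n_mirnas < 1:
            raise ValueError("cascades requested but n_mirnas is 0")

    @property
    def samples(self) -> list[str]:
        g1, g2 = self.group_labels
        return [f"{g1}{i+1}" for i in range(self.n_per_group[0])] + [
            f"{g2}{i+1}" for i in range(self.n_per_group[1])
        ]

    @property
    def sample_sheet(self) -> dict[str, str]:
        g1, g2 = self.group_labels
        out = {f"{g1}{i+1}": g1 for i in range(self.n_per_group[0])}
        out.update({f"{g2}{i+1}": g2 for i in range(self.n_per_group[1])})
        return out


@dataclass
class TruthTable:
    """Planted effects, one record per effect.

    Directions follow the pipeline's comparison convention group1 - group2:
    a planted "hyper" site has higher methylation in group 1, a positive
    planted log2fc means higher expression in group 1.
    """

    dms: pd.DataFrame          # chrom, pos, strand, direction, shift_pp, kind
    de_genes: pd.DataFrame     # gene_id, log2fc, kind
    de_mirnas: pd.DataFrame    # mirna_id, log2fc, kind
    coupled_genes: pd.DataFrame  # gene_id, meth_direction, expr_log2fc
    mirna_targets: pd.DataFrame  # mirna_id, gene_id (planted repression pairs)
    cascades: pd.DataFrame     # mirna_id, n_targets, target_ids (';'-joined)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    gtf_text: str
    models: list[GeneModel]
    methylation: MethylationTable
    gene_counts: CountTable
    mirna_counts: CountTable
    mirna_seqs: dict[str, str]
    utr_seqs: dict[str, str]
    truth: TruthTable


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig, rng: np.random.Generator) -> tuple[str, list[GeneModel]]:
    """Non-overlapping genes on a toy chromosome, with interspersed miRNA genes.

    Protein-coding genes get a 5'UTR (first 150 bp of the transcribed span on
    the gene's strand) and two exons; miRNA genes are short single-exon
    hairpins with no UTR.  Genes are spaced so that no promoter window
    reaches into a neighboring gene.
    """
    spacing_min = 4000
    models: list[GeneModel] = []
    lines: list[str] = []
    cursor = 5001
    n_total = config.n_genes + config.n_mirnas
    # deterministic interleaving: miRNA genes at evenly spread slots
    mirna_slots = set(
        np.linspace(0, n_total - 1, config.n_mirnas, dtype=int).tolist()
    ) if config.n_mirnas else set()
    gi = mi = 0
    for slot in range(n_total):
        strand = "+" if rng.random() < 0.5 else "-"
        if slot in mirna_slots:
            mi += 1
            gene_id = f"mir{mi}"
            length = 120
            start, end = cursor, cursor + length - 1
            exons = [(start, end)]
            utrs: list[tuple[int, int]] = []
            biotype = "miRNA"
        else:
            gi += 1
            gene_id = f"g{gi}"
            length = int(rng.integers(2500, 4500))
            start, end = cursor, cursor + length - 1
            if strand == "+":
                utrs = [(start, start + 149)]
                exons = [(start, start + 599), (end - 599, end)]
            else:
                utrs = [(end - 149, end)]
                exons = [(end - 599, end), (start, start + 599)]
            biotype = "protein_coding"
        model = GeneModel(
            gene_id=gene_id, chrom=CHROM, strand=strand, tx_start=start, tx_end=end,
            five_prime_utr=utrs, exons=exons, biotype=biotype,
        )
        models.append(model)
        attrs = f'gene_id "{gene_id}"; gene_biotype "{biotype}";'
        tattrs = f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1"; gene_biotype "{biotype}";'
        lines.append(f"{CHROM}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t.\t{attrs}")
        lines.append(f"{CHROM}\tsim\ttranscript\t{start}\t{end}\t.\t{strand}\t.\t{tattrs}")
        for a, b in sorted(model.exons):
            lines.append(f"{CHROM}\tsim\texon\t{a}\t{b}\t.\t{strand}\t.\t{tattrs}")
        for a, b in sorted(model.five_prime_utr):
            lines.append(f"{CHROM}\tsim\tfive_prime_utr\t{a}\t{b}\t.\t{strand}\t.\t{tattrs}")
        cursor = end + spacing_min + int(rng.integers(0, 500))
    return "\n".join(lines) + "\n", models


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _sample_positions(rng: np.random.Generator, intervals: list[tuple[int, int]], k: int) -> list[int]:
    lens = np.array([b - a + 1 for a, b in intervals])
    total = int(lens.sum())
    k = min(k, total)
    offsets = np.sort(rng.choice(total, size=k, replace=False))
    bounds = np.cumsum(lens)
    out = []
    for off in offsets:
        idx = int(np.searchsorted(bounds, off, side="right"))
        a, _ = intervals[idx]
        prev = 0 if idx == 0 else int(bounds[idx - 1])
        out.append(a + int(off) - prev)
    return out


def _group_latent(rng: np.random.Generator, n_per_group: tuple[int, int]) -> np.ndarray:
    from scipy import stats as _stats

    parts = []
    for n in n_per_group:
        scores = _stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
        scores = (scores - scores.mean()) / scores.std()
        parts.append(rng.permutation(scores))
    return np.concatenate(parts)


def simulate_methylome(
    config: SimulationConfig, models: list[GeneModel], rng: np.random.Generator
) -> tuple[MethylationTable, pd.DataFrame, dict]:
    """Beta-binomial methylome with planted differential sites.

    Returns the methylation table, the planted-DMS truth frame, and a layout
    dict used by the expression simulator (coupled genes, cascade miRNAs and
    their promoter site indices, per-sample latent factors).
    """
    n1, n2 = config.n_per_group
    n_samples = n1 + n2
    index = RegionIndex(models)
    coding = [m for m in models if m.biotype != "miRNA"]
    mirnas = [m for m in models if m.biotype == "miRNA"]

    site_rows = []  # (chrom, pos, strand, baseline, gene_id, region)
    n_prom = max(1, config.n_cpg_per_gene // 3)
    n_body = max(1, config.n_cpg_per_gene - n_prom)
    for m in models:
        reg = index.regions[m.gene_id]
        k_prom = n_prom if m.biotype != "miRNA" else 3
        for pos in _sample_positions(rng, reg.promoter, k_prom):
            site_rows.append([CHROM, pos, "+", config.promoter_baseline, m.gene_id, "promoter"])
        if m.biotype != "miRNA":
            for pos in _sample_positions(rng, reg.gene_body, n_body):
                site_rows.append([CHROM, pos, "+", config.body_baseline, m.gene_id, "gene_body"])
    # intergenic CpGs in the tail gap beyond the last gene
    last_end = max(m.tx_end for m in models)
    inter_pos = sorted(
        rng.choice(np.arange(last_end + 2000, last_end + 2000 + 50 * config.n_intergenic_cpg),
                   size=config.n_intergenic_cpg, replace=False).tolist()
    )
    for pos in inter_pos:
        site_rows.append([CHROM, int(pos), "+", config.body_baseline, "", "intergenic"])

    layout = pd.DataFrame(site_rows, columns=["chrom", "pos", "strand", "baseline", "gene_id", "region"])
    layout = layout.drop_duplicates(subset=["chrom", "pos", "strand"]).sort_values("pos").reset_index(drop=True)
    n_sites = len(layout)

    # --- choose planted structure ---------------------------------------
    coupled = [m.gene_id for m in coding[: config.n_coupled_genes]]
    coupled_dirs = {g: (1 if rng.random() < 0.5 else -1) for g in coupled}
    cascade_mirnas = [m.gene_id for m in mirnas[: config.n_cascades]]

    shift = np.zeros(n_sites)
    kind = np.array(["none"] * n_sites, dtype=object)
    # coupled promoters: all promoter CpGs of the gene shift together
    for g, d in coupled_dirs.items():
        mask = (layout["gene_id"] == g) & (layout["region"] == "promoter")
        shift[mask.to_numpy()] = d * config.dms_shift_pp / 100.0
        kind[mask.to_numpy()] = "coupled_promoter"
    # cascade miRNA promoters: hyper in group 1
    for g in cascade_mirnas:
        mask = (layout["gene_id"] == g) & (layout["region"] == "promoter")
        shift[mask.to_numpy()] = config.dms_shift_pp / 100.0
        kind[mask.to_numpy()] = "cascade_promoter"
    # free-standing DMSs among the untouched sites
    free = np.flatnonzero(kind == "none")
    n_dms = int(round(config.dms_fraction * n_sites))
    picked = rng.choice(free, size=min(n_dms, free.size), replace=False)
    signs = rng.choice([-1.0, 1.0], size=picked.size)
    shift[picked] = signs * config.dms_shift_pp / 100.0
    kind[picked] = "dms"

    # --- draw counts ------------------------------------------------------
    # shared cascade latent: within-group standardized normal scores in random
    # per-group order, so the latent has zero mean inside each group (planted
    # group fold changes stay exact) with a stable within-group spread that
    # carries the rank anti-coupling
    latent = _group_latent(rng, (n1, n2))
    base = np.clip(
        layout["baseline"].to_numpy() + rng.normal(scale=0.03, size=n_sites), 0.02, 0.98
    )
    # realize the planted group1 - group2 difference exactly: slide the
    # baseline so both group proportions stay inside (0.01, 0.99)
    lo = np.clip(base, 0.01, 0.99 - np.abs(shift))
    group1_p = np.where(shift >= 0, lo + shift, lo)
    group2_p = np.where(shift >= 0, lo, lo - shift)
    p_group = np.column_stack([np.repeat(group1_p[:, None], n1, axis=1),
                               np.repeat(group2_p[:, None], n2, axis=1)])
    is_cascade_prom = kind == "cascade_promoter"
    if is_cascade_prom.any():
        delta = (config.cascade_meth_latent_pp / 100.0) * latent
        p_group[is_cascade_prom] = np.clip(p_group[is_cascade_prom] + delta[None, :], 0.01, 0.99)

    cov = rng.negative_binomial(
        config.coverage_size,
        config.coverage_size / (config.coverage_size + config.coverage_mean),
        size=(n_sites, n_samples),
    ) + 1
    prec = config.bb_precision
    p_draw = rng.beta(p_group * prec, (1.0 - p_group) * prec)
    meth = rng.binomial(cov, p_draw)

    samples = config.samples
    table = MethylationTable(
        sites=layout[["chrom", "pos", "strand"]].copy(),
        coverage=pd.DataFrame(cov, columns=samples),
        methylated=pd.DataFrame(meth, columns=samples),
        group_of=config.sample_sheet,
    )
    planted = shift != 0.0
    truth_dms = pd.DataFrame(
        {
            "chrom": layout.loc[planted, "chrom"].to_numpy(),
            "pos": layout.loc[planted, "pos"].to_numpy(),
            "strand": layout.loc[planted, "strand"].to_numpy(),
            "direction": np.where(shift[planted] > 0, "hyper", "hypo"),
            "shift_pp": shift[planted] * 100.0,
            "kind": kind[planted],
        }
    ).reset_index(drop=True)
    info = {
        "coupled_dirs": coupled_dirs,
        "cascade_mirnas": cascade_mirnas,
        "latent": latent,
        "layout": layout.assign(kind=kind, shift=shift),
    }
    return table, truth_dms, info


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    size = 1.0 / max(alpha, 1e-8)
    return rng.negative_binomial(size, size / (size + np.maximum(mu, 1e-9)))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(SEED_ALPHABET[rng.integers(0, 4, size=length)])


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def simulate_expression(
    config: SimulationConfig,
    models: list[GeneModel],
    info: dict,
    rng: np.random.Generator,
) -> tuple[CountTable, CountTable, dict[str, str], dict[str, str], TruthTable]:
    """NB count matrices plus sequences, wired to the planted methylome.

    Planted log2 fold changes are group1 vs group2.  Coupled genes move
    opposite to their promoter methylation shift; cascade miRNAs drop and
    their targets rise, and a shared per-sample latent factor makes the
    miRNA-target rank correlation strongly negative within groups as well.
    """
    n1, n2 = config.n_per_group
    n_samples = n1 + n2
    samples = config.samples
    coding = [m.gene_id for m in models if m.biotype != "miRNA"]
    mirnas = [m.gene_id for m in models if m.biotype == "miRNA"]
    coupled_dirs: dict[str, int] = info["coupled_dirs"]
    cascade_mirnas: list[str] = info["cascade_mirnas"]
    latent: np.ndarray = info["latent"]

    # cascade targets drawn from genes free of other planted effects
    reserved = set(coupled_dirs)
    cascade_targets: dict[str, list[str]] = {}
    free_genes = [g for g in coding if g not in reserved]
    for mir in cascade_mirnas:
        tg = free_genes[: config.n_targets_per_cascade]
        free_genes = free_genes[config.n_targets_per_cascade :]
        cascade_targets[mir] = tg
        reserved.update(tg)

    lfc_gene = {g: 0.0 for g in coding}
    kind_gene = {g: "none" for g in coding}
    for g, d in coupled_dirs.items():
        lfc_gene[g] = -d * config.promoter_coupling_strength
        kind_gene[g] = "coupled"
    for mir, tgts in cascade_targets.items():
        for g in tgts:
            lfc_gene[g] = config.de_log2fc
            kind_gene[g] = "cascade_target"
    dms_free = [g for g in coding if g not in reserved]
    n_de = int(round(config.de_fraction * len(coding)))
    de_pick = list(rng.choice(dms_free, size=min(n_de, len(dms_free)), replace=False))
    for g in de_pick:
        lfc_gene[g] = float(rng.choice([-1.0, 1.0])) * config.de_log2fc
        kind_gene[g] = "de"

    lfc_mir = {m: 0.0 for m in mirnas}
    kind_mir = {m: "none" for m in mirnas}
    for mir in cascade_mirnas:
        lfc_mir[mir] = -config.de_log2fc
        kind_mir[mir] = "cascade_mirna"
    other_mirs = [m for m in mirnas if m not in cascade_mirnas]
    n_de_mir = int(round(config.de_fraction * len(mirnas)))
    for m in list(rng.choice(other_mirs, size=min(n_de_mir, len(other_mirs)), replace=False)):
        lfc_mir[m] = float(rng.choice([-1.0, 1.0])) * config.de_log2fc
        kind_mir[m] = "de"

    depth = np.exp(rng.normal(scale=config.depth_sdlog, size=n_samples))
    group_sign = np.array([0.5] * n1 + [-0.5] * n2)  # lfc split symmetrically

    def expr_matrix(feature_ids: list[str], lfc_map: dict[str, float], latent_sign: dict[str, float]):
        base = np.exp(rng.normal(config.expr_meanlog, config.expr_sdlog, size=len(feature_ids)))
        mu = base[:, None] * 2.0 ** (
            np.array([lfc_map[f] for f in feature_ids])[:, None] * group_sign[None, :]
        )
        lat = np.array([latent_sign.get(f, 0.0) for f in feature_ids])
        mu = mu * 2.0 ** (lat[:, None] * config.cascade_latent_strength * latent[None, :])
        mu = mu * depth[None, :]
        counts = _nb_counts(rng, mu, config.expr_dispersion)
        return pd.DataFrame(counts, index=feature_ids, columns=samples)

    latent_sign_genes = {g: 1.0 for tgts in cascade_targets.values() for g in tgts}
    latent_sign_mirs = {m: -1.0 for m in cascade_mirnas}
    gene_mat = expr_matrix(coding, lfc_gene, latent_sign_genes)
    mir_mat = expr_matrix(mirnas, lfc_mir, latent_sign_mirs)

    gene_counts = CountTable(counts=gene_mat, group_of=config.sample_sheet)
    mirna_counts = CountTable(counts=mir_mat, group_of=config.sample_sheet)

    # --- sequences: plant 7mer-m8 seed sites in cascade-target UTRs -------
    mirna_seqs = {m: _random_seq(rng, 22) for m in mirnas}
    utr_seqs = {}
    for g in coding:
        utr_seqs[g] = _random_seq(rng, config.utr_seq_length)
    for mir, tgts in cascade_targets.items():
        site = _revcomp(mirna_seqs[mir][1:8])
        for g in tgts:
            s = utr_seqs[g]
            mid = len(s) // 2
            utr_seqs[g] = s[:mid] + site + s[mid + len(site):]

    truth = TruthTable(
        dms=info["truth_dms"],
        de_genes=pd.DataFrame(
            [(g, lfc_gene[g], kind_gene[g]) for g in coding if lfc_gene[g] != 0.0],
            columns=["gene_id", "log2fc", "kind"],
        ),
        de_mirnas=pd.DataFrame(
            [(m, lfc_mir[m], kind_mir[m]) for m in mirnas if lfc_mir[m] != 0.0],
            columns=["mirna_id", "log2fc", "kind"],
        ),
        coupled_genes=pd.DataFrame(
            [(g, "hyper" if d > 0 else "hypo", -d * config.promoter_coupling_strength)
             for g, d in coupled_dirs.items()],
            columns=["gene_id", "meth_direction", "expr_log2fc"],
        ),
        mirna_targets=pd.DataFrame(
            [(mir, g) for mir, tgts in cascade_targets.items() for g in tgts],
            columns=["mirna_id", "gene_id"],
        ),
        cascades=pd.DataFrame(
            [(mir, len(tgts), ";".join(tgts)) for mir, tgts in cascade_targets.items()],
            columns=["mirna_id", "n_targets", "target_ids"],
        ),
    )
    return gene_counts, mirna_counts, mirna_seqs, utr_seqs, truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """End-to-end deterministic simulation under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    gtf_text, models = simulate_annotation(config, rng)
    meth_table, truth_dms, info = simulate_methylome(config, models, rng)
    info["truth_dms"] = truth_dms
    gene_counts, mirna_counts, mirna_seqs, utr_seqs, truth = simulate_expression(
        config, models, info, rng
    )
    return SimulatedDataset(
        config=config,
        gtf_text=gtf_text,
        models=models,
        methylation=meth_table,
        gene_counts=gene_counts,
        mirna_counts=mirna_counts,
        mirna_seqs=mirna_seqs,
        utr_seqs=utr_seqs,
        truth=truth,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Emit the dataset in exactly the dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "annotation.gtf").write_text(ds.gtf_text)
    write_methylation_table(ds.methylation, outdir / "methylation.tsv")
    write_count_table(ds.gene_counts, outdir / "gene_counts.tsv")
    write_count_table(ds.mirna_counts, outdir / "mirna_counts.tsv")
    with open(outdir / "mirna.fa", "w") as fh:
        for name in sorted(ds.mirna_seqs):
            fh.write(f">{name}\n{ds.mirna_seqs[name]}\n")
    with open(outdir / "utr.fa", "w") as fh:
        for name in sorted(ds.utr_seqs):
            fh.write(f">{name}\n{ds.utr_seqs[name]}\n")
    sheet = pd.DataFrame(
        sorted(ds.config.sample_sheet.items()), columns=["sample", "group"]
    )
    sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    ds.truth.dms.to_csv(outdir / "truth_dms.tsv", sep="\t", index=False)
    ds.truth.de_genes.to_csv(outdir / "truth_de_genes.tsv", sep="\t", index=False)
    ds.truth.de_mirnas.to_csv(outdir / "truth_de_mirnas.tsv", sep="\t", index=False)
    ds.truth.coupled_genes.to_csv(outdir / "truth_coupled_genes.tsv", sep="\t", index=False)
    ds.truth.mirna_targets.to_csv(outdir / "truth_mirna_targets.tsv", sep="\t", index=False)
    ds.truth.cascades.to_csv(outdir / "truth_cascades.tsv", sep="\t", index=False)
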