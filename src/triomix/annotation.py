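"""Strand-aware gene-region models and CpG-site assignment.

The promoter of a gene is defined as the TSS1500 window -- the 1,500 bp
strictly upstream of the transcription start site on the gene's strand --
unioned with any annotated 5'UTR intervals.  The gene body is the transcribed
span minus the 5'UTR; within the body, exonic bases come from the (merged)
exon union and everything else is intronic.  Multi-transcript genes are
collapsed to gene level: exon/UTR unions, one TSS at the 5'-most transcribed
position on the strand.

All intervals are 1-based inclusive internally.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from intervaltree import IntervalTree

from .io_formats import DataError

__all__ = [
    "GeneModel",
    "RegionIndex",
    "load_gene_models",
    "derive_regions",
    "assign_site",
    "merge_intervals",
    "subtract_intervals",
]

Interval = tuple[int, int]  # 1-based inclusive

PROMOTER = "promoter"
EXON = "exon"
INTRON = "intron"
GENE_BODY = "gene_body"
INTERGENIC = "intergenic"


def merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping or bookended 1-based inclusive intervals."""
    ivs = sorted((int(a), int(b)) for a, b in ivs)
    out: list[Interval] = []
    for a, b in ivs:
        if a > b:
            raise DataError(f"invalid interval [{a},{b}]")
        if out and a <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def subtract_intervals(base: Sequence[Interval], minus: Sequence[Interval]) -> list[Interval]:
    """Set difference base \\ minus on merged 1-based inclusive intervals."""
    base = merge_intervals(base)
    minus = merge_intervals(minus)
    out: list[Interval] = []
    for a, b in base:
        cur = a
        for ma, mb in minus:
            if mb < cur or ma > b:
                continue
            if ma > cur:
                out.append((cur, ma - 1))
            cur = max(cur, mb + 1)
            if cur > b:
                break
        if cur <= b:
            out.append((cur, b))
    return out


def intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    for x0, x1 in a:
        for y0, y1 in b:
            lo, hi = max(x0, y0), min(x1, y1)
            if lo <= hi:
                out.append((lo, hi))
    return merge_intervals(out) if out else []


@dataclass
class GeneModel:
    """A gene collapsed to one strand-aware transcribed span with exon/UTR unions."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    five_prime_utr: list[Interval] = field(default_factory=list)
    exons: list[Interval] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if self.tx_start > self.tx_end:
            raise DataError(f"gene {self.gene_id}: tx_start > tx_end")
        self.exons = merge_intervals(self.exons) if self.exons else []
        self.five_prime_utr = merge_intervals(self.five_prime_utr) if self.five_prime_utr else []
        for a, b in self.exons + self.five_prime_utr:
            if a < self.tx_start or b > self.tx_end:
                raise DataError(f"gene {self.gene_id}: interval [{a},{b}] outside span")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end


@dataclass
class GeneRegions:
    """Derived region partition of one gene."""

    gene_id: str
    chrom: str
    strand: str
    promoter: list[Interval]
    gene_body: list[Interval]
    exon: list[Interval]
    intron: list[Interval]


def derive_regions(model: GeneModel, tss_window: int = 1500) -> GeneRegions:
    """Partition a gene into promoter / gene-body exon / gene-body intron.

    The upstream window is [TSS-1500, TSS-1] on + genes and [TSS+1, TSS+1500]
    on - genes, i.e. strictly upstream of (exclusive of) the TSS base; the
    TSS base itself starts the 5'UTR when one is annotated.  Coordinates are
    clipped at 1.
    """
    if tss_window <= 0:
        raise ValueError(f"tss_window must be positive, got {tss_window}")
    tss = model.tss
    if model.strand == "+":
        upstream = (max(1, tss - tss_window), tss - 1)
    else:
        upstream = (tss + 1, tss + tss_window)
    window = [upstream] if upstream[0] <= upstream[1] else []
    promoter = merge_intervals(window + model.five_prime_utr)
    span = [(model.tx_start, model.tx_end)]
    body = subtract_intervals(span, model.five_prime_utr)
    exon = intersect_intervals(model.exons, body) if model.exons else []
    intron = subtract_intervals(body, exon)
    return GeneRegions(
        gene_id=model.gene_id,
        chrom=model.chrom,
        strand=model.strand,
        promoter=promoter,
        gene_body=body,
        exon=exon,
        intron=intron,
    )


class RegionIndex:
    """Per-chromosome interval lookup from position to (gene_id, region).

    Regions are gene-strand-defined; CpG strand is deliberately ignored at
    lookup.  A position covered by no gene's promoter or body is intergenic.
    """

    def __init__(self, models: Iterable[GeneModel], tss_window: int = 1500):
        self.tss_window = tss_window
        self.regions: dict[str, GeneRegions] = {}
        self._trees: dict[str, IntervalTree] = {}
        for model in models:
            reg = derive_regions(model, tss_window)
            if model.gene_id in self.regions:
                raise DataError(f"duplicate gene id {model.gene_id}")
            self.regions[model.gene_id] = reg
            tree = self._trees.setdefault(model.chrom, IntervalTree())
            for label, ivs in ((PROMOTER, reg.promoter), (EXON, reg.exon), (INTRON, reg.intron)):
                for a, b in ivs:
                    # intervaltree is half-open; store 1-based inclusive as [a, b+1)
                    tree.addi(a, b + 1, (model.gene_id, label))

    def assign(self, chrom: str, pos: int) -> list[tuple[str, str]]:
        """All (gene_id, region) assignments for a 1-based position; [] = intergenic."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.at(int(pos)))
        return hits


def assign_site(
    site: tuple[str, int, str], index: RegionIndex
) -> tuple[list[tuple[str, str]], bool]:
    """Assign one CpG site; returns (assignments, intergenic flag).

    ``site`` is (chrom, pos, strand); the CpG strand does not influence
    assignment because regions are defined by the gene's strand.
    """
    chrom, pos, _strand = site
    hits = index.assign(chrom, pos)
    return hits, not hits


def load_gene_models(gtf_path: str | Path, biotype_attr: str = "gene_biotype") -> list[GeneModel]:
    """Load gene-level collapsed models from a GTF/GFF3 file.

    Multi-transcript genes collapse to the union of exons and of 5'UTRs with
    a single TSS at the 5'-most transcribed position on the gene's strand.
    """
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models: list[GeneModel] = []
    genes = list(db.features_of_type("gene"))
    if not genes:
        # GFF3 dialects may type genes differently; fall back to any feature
        # carrying a gene_id but no Parent.
        raise DataError(f"{gtf_path}: no gene features found")
    for gene in genes:
        if gene.strand not in ("+", "-"):
            raise DataError(f"gene {gene.id}: missing or invalid strand")
        gene_id = gene.attributes.get("gene_id", [gene.id])[0]
        exons = []
        utrs = []
        start, end = gene.start, gene.end
        for child in db.children(gene.id):
            start = min(start, child.start)
            end = max(end, child.end)
            if child.featuretype == "exon":
                exons.append((child.start, child.end))
            elif child.featuretype in ("five_prime_utr", "five_prime_UTR", "5UTR"):
                utrs.append((child.start, child.end))
        biotype = gene.attributes.get(biotype_attr, ["protein_coding"])[0]
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=gene.seqid,
                strand=gene.strand,
                tx_start=start,
                tx_end=end,
                five_prime_utr=utrs,
                exons=exons,
                biotype=biotype,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.tx_start, m.gene_id))
    return models


def load_gene_models_from_text(gtf_text: str) -> list[GeneModel]:
    """Convenience wrapper: parse GTF given as a string (used with simulated GTFs)."""
    with tempfile.NamedTemporaryFile("w", suffix=".gtf", delete=False) as fh:
        fh.write(gtf_text)
        path = fh.name
    try:
        return load_gene_models(path)
    finally:
        Path(path).unlink(missing_ok=True)
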