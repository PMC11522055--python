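import numpy as np
import pandas as pd
import pytest

from triomix.io_formats import CountTable, MethylationTable


@pytest.fixture
def toy_methylation() -> MethylationTable:
    """Two groups x two samples, four CpG sites with hand-set counts."""
    sites = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "pos": [100, 200, 300, 50],
            "strand": ["+", "+", "-", "+"],
        }
    )
    cov = pd.DataFrame(
        {
            "A1": [20, 30, 25, 40],
            "A2": [22, 28, 30, 35],
            "B1": [18, 32, 20, 30],
            "B2": [25, 30, 28, 32],
        }
    )
    meth = pd.DataFrame(
        {
            "A1": [18, 3, 12, 20],
            "A2": [20, 2, 15, 18],
            "B1": [2, 29, 10, 15],
            "B2": [3, 28, 14, 16],
        }
    )
    return MethylationTable(
        sites=sites, coverage=cov, methylated=meth,
        group_of={"A1": "A", "A2": "A", "B1": "B", "B2": "B"},
    )


@pytest.fixture
def toy_counts() -> CountTable:
    counts = pd.DataFrame(
        {
            "A1": [100, 10, 500, 40],
            "A2": [120, 12, 450, 38],
            "B1": [25, 11, 480, 160],
            "B2": [30, 9, 520, 150],
        },
        index=["g_up", "g_flat_low", "g_flat_high", "g_down"],
    )
    counts.index.name = "feature_id"
    return CountTable(
        counts=counts, group_of={"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
    )


@pytest.fixture
def toy_gtf(tmp_path):
    """Two + strand genes and one - strand gene with UTRs/exons, plus a miRNA."""
    text = "\n".join(
        [
            'chr1\ttoy\tgene\t10000\t13999\t.\t+\t.\tgene_id "gA"; gene_biotype "protein_coding";',
            'chr1\ttoy\ttranscript\t10000\t13999\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
            'chr1\ttoy\texon\t10000\t10599\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
            'chr1\ttoy\texon\t13400\t13999\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
            'chr1\ttoy\tfive_prime_utr\t10000\t10199\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";',
            'chr1\ttoy\tgene\t20000\t24999\t.\t-\t.\tgene_id "gB"; gene_biotype "protein_coding";',
            'chr1\ttoy\ttranscript\t20000\t24999\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";',
            'chr1\ttoy\texon\t24400\t24999\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";',
            'chr1\ttoy\texon\t20000\t20599\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";',
            'chr1\ttoy\tfive_prime_utr\t24800\t24999\t.\t-\t.\tgene_id "gB"; transcript_id "gB.t1";',
            'chr1\ttoy\tgene\t30000\t30119\t.\t+\t.\tgene_id "mirX"; gene_biotype "miRNA";',
            'chr1\ttoy\ttranscript\t30000\t30119\t.\t+\t.\tgene_id "mirX"; transcript_id "mirX.t1";',
            'chr1\ttoy\texon\t30000\t30119\t.\t+\t.\tgene_id "mirX"; transcript_id "mirX.t1";',
        ]
    )
    path = tmp_path / "toy.gtf"
    path.write_text(text + "\n")
    return path


def brute_force_assign(models, tss_window, chrom, pos):
    """Independent linear-scan oracle for region assignment."""
    hits = []
    for m in models:
        if m.chrom != chrom:
            continue
        tss = m.tx_start if m.strand == "+" else m.tx_end
        if m.strand == "+":
            window = (max(1, tss - tss_window), tss - 1)
        else:
            window = (tss + 1, tss + tss_window)
        in_prom = window[0] <= pos <= window[1] or any(
            a <= pos <= b for a, b in m.five_prime_utr
        )
        if in_prom:
            hits.append((m.gene_id, "promoter"))
            continue
        if m.tx_start <= pos <= m.tx_end and not any(
            a <= pos <= b for a, b in m.five_prime_utr
        ):
            if any(a <= pos <= b for a, b in m.exons):
                hits.append((m.gene_id, "exon"))
            else:
                hits.append((m.gene_id, "intron"))
    return sorted(hits)
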