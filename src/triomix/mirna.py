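"""miRNA layer: target prediction stand-in, anti-correlation filtering, and
methylation -> miRNA -> mRNA regulatory-chain construction.

Target prediction is a transparent canonical-seed match: a miRNA targets a
gene when the reverse complement of its seed (nucleotides 2-8, the 7mer-m8
site) occurs in the gene's 3'UTR, given 5'->3'.  A user-supplied target map
bypasses prediction entirely.

A miRNA-target pair is retained when the Spearman correlation of their
per-sample normalized expression is below -0.9 and the target is
differentially expressed.  A regulatory chain links a promoter DMS of a
miRNA gene to the miRNA's expression change and onward to its
anti-correlated targets; all negative target correlations are reported,
with the r < -0.9 subset flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import PROMOTER, RegionIndex
from .diff_methylation import HYPER, HYPO
from .integration import spearman
from .io_formats import ConfigurationError, DataError, MethylationTable, TargetMap

__all__ = [
    "predict_targets_seed",
    "correlate_pairs",
    "mirna_promoter_dms",
    "build_chains",
    "RegulatoryChain",
]

log = logging.getLogger(__name__)

TARGET_R_CUTOFF = -0.9
_VALID = set("ACGTU")


def _normalize_seq(seq: str, name: str) -> str:
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - set("ACGT")
    if bad:
        raise DataError(f"{name}: non-ACGTU symbol(s) {sorted(bad)}")
    return s


def predict_targets_seed(
    mirna_seqs: dict[str, str], utr_seqs: dict[str, str], seed_start: int = 2, seed_end: int = 8
) -> TargetMap:
    """7mer-m8 canonical seed matching of miRNAs against 3'UTRs.

    ``mirna_seqs`` maps miRNA id -> mature sequence (RNA or DNA alphabet),
    ``utr_seqs`` gene id -> 3'UTR sequence given 5'->3'.  A pair is emitted
    when the reverse complement of the miRNA seed (nt ``seed_start``..
    ``seed_end``, 1-based, default 2-8) occurs in the UTR; the match count
    is recorded.  Empty UTRs are skipped.
    """
    rows = []
    for gene_id in sorted(utr_seqs):
        utr_raw = utr_seqs[gene_id]
        if not utr_raw:
            log.info("gene %s: empty 3'UTR, skipped", gene_id)
            continue
        utr = _normalize_seq(utr_raw, f"UTR {gene_id}")
        for mirna_id in sorted(mirna_seqs):
            mir = _normalize_seq(mirna_seqs[mirna_id], f"miRNA {mirna_id}")
            if len(mir) < seed_end:
                raise DataError(f"miRNA {mirna_id}: shorter than seed end {seed_end}")
            seed = mir[seed_start - 1 : seed_end]
            site = str(Seq(seed).reverse_complement())
            n = utr.count(site)
            if n > 0:
                rows.append(
                    {"mirna_id": mirna_id, "gene_id": gene_id, "source": "seed_match", "n_sites": n}
                )
    df = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "source", "n_sites"])
    return TargetMap(pairs=df)


def correlate_pairs(
    target_map: TargetMap,
    mirna_norm: pd.DataFrame,
    gene_norm: pd.DataFrame,
    gene_de: pd.DataFrame,
    samples: list[str],
    r_cutoff: float = TARGET_R_CUTOFF,
) -> pd.DataFrame:
    """Spearman anti-correlation filter over predicted miRNA-target pairs.

    Correlates each mapped pair's normalized expression across ``samples``
    (which must be present in both matrices).  A pair is ``retained`` when
    r < ``r_cutoff`` and the target gene is DE.  Returns all evaluated pairs
    with columns mirna_id, gene_id, r, p, target_is_de, retained.
    """
    missing = [s for s in samples if s not in mirna_norm.columns or s not in gene_norm.columns]
    if missing:
        raise ConfigurationError(f"samples absent from expression matrices: {missing}")
    rows = []
    for _, rec in target_map.pairs.iterrows():
        mirna_id, gene_id = rec["mirna_id"], rec["gene_id"]
        if mirna_id not in mirna_norm.index or gene_id not in gene_norm.index:
            continue
        x = mirna_norm.loc[mirna_id, samples].to_numpy(dtype=float)
        y = gene_norm.loc[gene_id, samples].to_numpy(dtype=float)
        r, p = spearman(x, y)
        is_de = bool(gene_de.loc[gene_id, "is_de"]) if gene_id in gene_de.index else False
        rows.append(
            {
                "mirna_id": mirna_id,
                "gene_id": gene_id,
                "r": r,
                "p": p,
                "target_is_de": is_de,
                "retained": bool(not np.isnan(r) and r < r_cutoff and is_de),
            }
        )
    return pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "r", "p", "target_is_de", "retained"]
    )


def mirna_promoter_dms(index: RegionIndex, dms: pd.DataFrame, mirna_ids: set[str]) -> dict[str, pd.DataFrame]:
    """Map each miRNA gene to the called DMSs overlapping its promoter."""
    out: dict[str, list] = {}
    called = dms[dms["direction"].isin([HYPER, HYPO])]
    for _, rec in called.iterrows():
        for gene_id, region in index.assign(str(rec["chrom"]), int(rec["pos"])):
            if region == PROMOTER and gene_id in mirna_ids:
                out.setdefault(gene_id, []).append(rec)
    return {k: pd.DataFrame(v).reset_index(drop=True) for k, v in out.items()}


@dataclass
class RegulatoryChain:
    """Promoter DMS -> miRNA expression change -> anti-correlated targets."""

    mirna_id: str
    promoter_dms: pd.DataFrame
    mirna_log2fc: float
    mirna_padj: float
    meth_mirna_r: float
    meth_mirna_p: float
    target_links: pd.DataFrame  # gene_id, r, p, gene_log2fc, passes_cutoff

    def to_rows(self) -> list[dict]:
        """One flat row per miRNA-target link (for the chain report TSV)."""
        dms_keys = ";".join(
            f"{r['chrom']}:{r['pos']}:{r['strand']}({r['direction']})"
            for _, r in self.promoter_dms.iterrows()
        )
        rows = []
        for _, t in self.target_links.iterrows():
            rows.append(
                {
                    "mirna_id": self.mirna_id,
                    "promoter_dms": dms_keys,
                    "n_promoter_dms": len(self.promoter_dms),
                    "mirna_log2fc": self.mirna_log2fc,
                    "mirna_padj": self.mirna_padj,
                    "meth_mirna_r": self.meth_mirna_r,
                    "meth_mirna_p": self.meth_mirna_p,
                    "gene_id": t["gene_id"],
                    "target_r": t["r"],
                    "target_p": t["p"],
                    "gene_log2fc": t["gene_log2fc"],
                    "passes_cutoff": bool(t["passes_cutoff"]),
                }
            )
        if not rows:
            rows.append(
                {
                    "mirna_id": self.mirna_id,
                    "promoter_dms": dms_keys,
                    "n_promoter_dms": len(self.promoter_dms),
                    "mirna_log2fc": self.mirna_log2fc,
                    "mirna_padj": self.mirna_padj,
                    "meth_mirna_r": self.meth_mirna_r,
                    "meth_mirna_p": self.meth_mirna_p,
                    "gene_id": "",
                    "target_r": float("nan"),
                    "target_p": float("nan"),
                    "gene_log2fc": float("nan"),
                    "passes_cutoff": False,
                }
            )
        return rows


def build_chains(
    promoter_map: dict[str, pd.DataFrame],
    mirna_de: pd.DataFrame,
    pairs: pd.DataFrame,
    meth_table: MethylationTable,
    mirna_norm: pd.DataFrame,
    gene_de: pd.DataFrame,
    samples: list[str],
    r_cutoff: float = TARGET_R_CUTOFF,
) -> list[RegulatoryChain]:
    """Assemble regulatory chains for miRNAs with promoter DMSs.

    A chain is emitted when the miRNA (i) has >= 1 promoter DMS, (ii) is DE,
    (iii) its mean promoter-DMS methylation anti-correlates with its
    expression across samples (r < 0), and (iv) >= 1 mapped target shows a
    negative expression correlation.  All negative target links are reported;
    ``passes_cutoff`` marks the r < ``r_cutoff`` subset.
    """
    chains: list[RegulatoryChain] = []
    pct = meth_table.percent_methylation()
    keys = meth_table.site_keys()
    for mirna_id in sorted(promoter_map):
        dms = promoter_map[mirna_id]
        if mirna_id not in mirna_de.index or not bool(mirna_de.loc[mirna_id, "is_de"]):
            continue
        site_mask = keys.isin(
            [f"{r['chrom']}:{r['pos']}:{r['strand']}" for _, r in dms.iterrows()]
        )
        prom_pct = pct.loc[site_mask, samples].mean(axis=0).to_numpy(dtype=float)
        if mirna_id not in mirna_norm.index:
            continue
        expr = mirna_norm.loc[mirna_id, samples].to_numpy(dtype=float)
        ok = ~np.isnan(prom_pct) & ~np.isnan(expr)
        if ok.sum() < 3:
            continue
        r, p = spearman(prom_pct[ok], expr[ok])
        if np.isnan(r) or r >= 0:
            continue
        links = pairs[(pairs["mirna_id"] == mirna_id) & (pairs["r"] < 0) & pairs["target_is_de"]]
        if links.empty:
            continue
        link_rows = []
        for _, t in links.iterrows():
            lfc = (
                float(gene_de.loc[t["gene_id"], "log2fc"]) if t["gene_id"] in gene_de.index else float("nan")
            )
            link_rows.append(
                {
                    "gene_id": t["gene_id"],
                    "r": float(t["r"]),
                    "p": float(t["p"]),
                    "gene_log2fc": lfc,
                    "passes_cutoff": bool(t["r"] < r_cutoff),
                }
            )
        chains.append(
            RegulatoryChain(
                mirna_id=mirna_id,
                promoter_dms=dms,
                mirna_log2fc=float(mirna_de.loc[mirna_id, "log2fc"]),
                mirna_padj=float(mirna_de.loc[mirna_id, "padj"]),
                meth_mirna_r=r,
                meth_mirna_p=p,
                target_links=pd.DataFrame(
                    link_rows, columns=["gene_id", "r", "p", "gene_log2fc", "passes_cutoff"]
                ).sort_values("gene_id").reset_index(drop=True),
            )
        )
    return chains
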