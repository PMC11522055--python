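"""Methylation-expression integration.

Each differentially methylated site (DMS) is paired with every gene whose
promoter or body it overlaps, carrying the site's methylation difference and
the gene's expression difference, fold change, adjusted p and expression
tier.  Pairs are then stratified by tier x region x methylation direction and
each stratum is summarized by its counts, mean differences, and the Spearman
correlation of (methylation difference, expression difference) across the
stratum's CpG-gene pairs.

"Methylation-dependent" genes are selected by the canonical sign rules:
promoter methylation is expected to repress (hyper DMS with the gene down,
or hypo with the gene up), gene-body methylation to track expression
(directions matching).
"""

from __future__ import annotations

import itertools
import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import PROMOTER, RegionIndex
from .diff_methylation import HYPER, HYPO
from .io_formats import ConfigurationError

__all__ = [
    "spearman",
    "build_pairs",
    "stratum_table",
    "select_methylation_dependent",
    "cross_comparison_sets",
]

log = logging.getLogger(__name__)

GENE_BODY = "gene_body"
EXACT_PERMUTATION_MAX_N = 8  # exhaustive n! enumeration up to 8 samples


@lru_cache(maxsize=8)
def _permutation_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with an exact small-sample p-value.

    rho is the Pearson correlation of average ranks (so ties are handled).
    The two-sided p-value is computed by exhaustive enumeration of all n!
    rank pairings for n <= 8 and by the t-approximation with n-2 df above
    that.  A constant vector makes rho undefined (NaN, NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 observations, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    ssx = float(dx @ dx)
    ssy = float(dy @ dy)
    if ssx == 0.0 or ssy == 0.0:
        return float("nan"), float("nan")
    rho = float(dx @ dy) / np.sqrt(ssx * ssy)
    rho = float(np.clip(rho, -1.0, 1.0))
    if n <= EXACT_PERMUTATION_MAX_N:
        perms = _permutation_matrix(n)
        dy_perm = dy[perms]  # (n!, n)
        rho_perm = (dy_perm @ dx) / np.sqrt(ssx * ssy)
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def build_pairs(
    dms: pd.DataFrame,
    index: RegionIndex,
    expr_records: pd.DataFrame,
    norm_expr: pd.DataFrame,
    samples_group1: list[str],
    samples_group2: list[str],
) -> pd.DataFrame:
    """Pair each called DMS with its overlapping gene promoters/bodies.

    ``dms`` is the differential-methylation table (only rows with direction
    hyper/hypo are paired); ``expr_records`` the tier-annotated DE table;
    ``norm_expr`` normalized counts used for the expression difference
    (mean group1 - mean group2).  Genes absent from the expression table are
    dropped with a logged count.
    """
    called = dms[dms["direction"].isin([HYPER, HYPO])]
    expr_diff_all = (
        norm_expr[samples_group1].mean(axis=1) - norm_expr[samples_group2].mean(axis=1)
    )
    rows = []
    n_dropped = 0
    for _, rec in called.iterrows():
        hits = index.assign(str(rec["chrom"]), int(rec["pos"]))
        for gene_id, region in hits:
            coarse = PROMOTER if region == PROMOTER else GENE_BODY
            if gene_id not in expr_records.index:
                n_dropped += 1
                continue
            e = expr_records.loc[gene_id]
            rows.append(
                {
                    "chrom": rec["chrom"],
                    "pos": int(rec["pos"]),
                    "strand": rec["strand"],
                    "gene_id": gene_id,
                    "region": coarse,
                    "direction": rec["direction"],
                    "meth_diff": float(rec["meth_diff"]),
                    "expr_diff": float(expr_diff_all.get(gene_id, np.nan)),
                    "gene_log2fc": float(e["log2fc"]),
                    "gene_padj": float(e["padj"]),
                    "tier": e.get("tier", "unset"),
                }
            )
    if n_dropped:
        log.info("dropped %d DMS-gene pairs lacking expression data", n_dropped)
    cols = [
        "chrom", "pos", "strand", "gene_id", "region", "direction",
        "meth_diff", "expr_diff", "gene_log2fc", "gene_padj", "tier",
    ]
    return pd.DataFrame(rows, columns=cols)


_TIER_STRATA = [("all", None), ("Q3", "Q3"), ("Q2", "Q2"), ("Q1", "Q1")]
_REGION_STRATA = [("all", None), ("body", GENE_BODY), ("promoter", PROMOTER)]


def stratum_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Stratum summary: tier x region x direction rows over CpG-gene pairs.

    Per row: number of CpG-gene pairs (n_cpg), number of distinct genes,
    mean methylation difference (pp), mean expression difference (normalized
    counts), and the Spearman correlation (with significance) of
    (meth_diff, expr_diff) across the row's pairs.  Empty strata keep their
    row with zero counts and NaN statistics; rho needs >= 3 pairs.
    """
    rows = []
    for tier_label, tier in _TIER_STRATA:
        for region_label, region in _REGION_STRATA:
            for direction in (HYPER, HYPO):
                sub = pairs
                if tier is not None:
                    sub = sub[sub["tier"] == tier]
                if region is not None:
                    sub = sub[sub["region"] == region]
                sub = sub[sub["direction"] == direction]
                n = len(sub)
                if n >= 3:
                    rho, p = spearman(sub["meth_diff"].to_numpy(), sub["expr_diff"].to_numpy())
                else:
                    rho, p = float("nan"), float("nan")
                rows.append(
                    {
                        "tier": tier_label,
                        "region": region_label,
                        "direction": direction,
                        "n_cpg": n,
                        "n_genes": int(sub["gene_id"].nunique()),
                        "avg_meth_diff": float(sub["meth_diff"].mean()) if n else float("nan"),
                        "avg_expr_diff": float(sub["expr_diff"].mean()) if n else float("nan"),
                        "spearman_rho": rho,
                        "spearman_p": p,
                    }
                )
    return pd.DataFrame(rows)


def select_methylation_dependent(
    pairs: pd.DataFrame, max_padj: float = 0.05, min_abs_lfc: float = 1.0
) -> dict[str, pd.DataFrame]:
    """Genes whose significant expression change matches the canonical sign rule.

    promoter class: >= 1 promoter DMS opposing the expression change
    (hyper with log2fc < 0, hypo with log2fc > 0); gene-body class: >= 1 body
    DMS matching it.  Only genes with padj < max_padj and |log2fc| >=
    min_abs_lfc qualify.  Each gene appears once per class, labeled with the
    direction(s) of its qualifying DMSs ("hypermeth", "hypometh", or both).
    """
    sig = pairs[
        (pairs["gene_padj"] < max_padj) & (pairs["gene_log2fc"].abs() >= min_abs_lfc)
    ]
    out = {}
    for cls, region in (("promoter", PROMOTER), ("gene_body", GENE_BODY)):
        sub = sig[sig["region"] == region]
        if region == PROMOTER:
            ok = ((sub["direction"] == HYPER) & (sub["gene_log2fc"] < 0)) | (
                (sub["direction"] == HYPO) & (sub["gene_log2fc"] > 0)
            )
        else:
            ok = ((sub["direction"] == HYPER) & (sub["gene_log2fc"] > 0)) | (
                (sub["direction"] == HYPO) & (sub["gene_log2fc"] < 0)
            )
        sub = sub[ok]
        recs = []
        for gene_id, grp in sub.groupby("gene_id"):
            dirs = sorted(set(grp["direction"]))
            label = "+".join(f"{d}meth" for d in dirs)
            recs.append(
                {
                    "gene_id": gene_id,
                    "label": label,
                    "n_dms": len(grp),
                    "gene_log2fc": float(grp["gene_log2fc"].iloc[0]),
                    "gene_padj": float(grp["gene_padj"].iloc[0]),
                }
            )
        df = pd.DataFrame(recs, columns=["gene_id", "label", "n_dms", "gene_log2fc", "gene_padj"])
        out[cls] = df.sort_values("gene_id").reset_index(drop=True)
    return out


def cross_comparison_sets(gene_lists: dict[str, dict[str, str]]) -> pd.DataFrame:
    """Partition genes by exact comparison-membership pattern.

    ``gene_lists`` maps comparison name -> {gene_id: direction label}.
    Returns one row per gene with its membership pattern string (comparison
    and label, space-joined in sorted comparison order) and the number of
    comparisons it appears in.
    """
    if len(gene_lists) < 2:
        raise ConfigurationError("need >= 2 comparisons for a cross-comparison partition")
    comparisons = sorted(gene_lists)
    all_genes = sorted(set().union(*[set(d) for d in gene_lists.values()]))
    rows = []
    for gene in all_genes:
        members = [c for c in comparisons if gene in gene_lists[c]]
        pattern = " ".join(f"{c}_{gene_lists[c][gene]}" for c in members)
        rows.append(
            {
                "gene_id": gene,
                "n_comparisons": len(members),
                "membership": "&".join(members),
                "pattern": pattern,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_comparisons", "membership", "pattern"])
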