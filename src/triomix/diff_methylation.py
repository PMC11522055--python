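"""Per-CpG differential methylation between two tissue groups.

The test mirrors the standard RRBS two-group design: with one sample per
group (or when replicates are deliberately pooled) a two-sided Fisher exact
test on the pooled 2x2 methylated/unmethylated table; with replicates, a
likelihood-ratio test of the group effect in a binomial logistic regression
on per-sample (methylated, coverage) pairs.  For a single two-level factor
the binomial GLM maximum likelihood is attained at the coverage-pooled group
proportions, so the LRT statistic has a closed form and is computed
vectorized across sites; the statistic is identical to an iteratively fitted
logistic regression.

A site is a DMS when |mean percent difference| >= ``min_diff`` percentage
points (default 25) and its Benjamini-Hochberg q-value is < ``max_q``
(default 0.01).  In a comparison named "AvsB" the difference is
mean(A) - mean(B) and "hyper" means hypermethylated in A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .annotation import EXON, INTRON, PROMOTER, INTERGENIC, RegionIndex
from .io_formats import ConfigurationError, DataError, MethylationTable

__all__ = [
    "filter_coverage",
    "fisher_exact_two_sided",
    "lrt_two_group",
    "test_site",
    "adjust_pvalues",
    "call_dms",
    "dms_summary",
    "profile_correlation",
    "feature_distribution",
]

log = logging.getLogger(__name__)

HYPER = "hyper"
HYPO = "hypo"
NS = "ns"


def filter_coverage(
    table: MethylationTable, min_cov: int = 10, max_pctile: float = 99.9
) -> MethylationTable:
    """Keep sites where every sample has min_cov <= coverage <= its max_pctile cap.

    The upper percentile cap (computed per sample over that sample's covered
    sites) removes likely PCR-duplicated pile-ups, standard RRBS practice.
    """
    if min_cov < 1:
        raise ValueError(f"min_cov must be >= 1, got {min_cov}")
    cov = table.coverage.to_numpy(dtype=float)
    caps = np.nanpercentile(np.where(cov > 0, cov, np.nan), max_pctile, axis=0)
    caps = np.where(np.isnan(caps), np.inf, caps)
    keep = ((cov >= min_cov) & (cov <= caps)).all(axis=1)
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("coverage filter removed %d/%d sites", n_removed, len(keep))
    if not keep.any():
        log.warning("coverage filter removed every site")
    out = table.subset_sites(keep)
    return out


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

_TIE_EPS = 1e-7  # relative tolerance for pmf ties in the two-sided Fisher sum


def fisher_exact_two_sided(
    m1: np.ndarray, u1: np.ndarray, m2: np.ndarray, u2: np.ndarray
) -> np.ndarray:
    """Two-sided Fisher exact p for 2x2 tables [[m1, u1], [m2, u2]], vectorized.

    p is the hypergeometric probability mass of all tables with the observed
    margins whose probability does not exceed the observed table's (with a
    small relative tolerance for floating-point ties).
    """
    m1 = np.atleast_1d(np.asarray(m1, dtype=np.int64))
    u1 = np.atleast_1d(np.asarray(u1, dtype=np.int64))
    m2 = np.atleast_1d(np.asarray(m2, dtype=np.int64))
    u2 = np.atleast_1d(np.asarray(u2, dtype=np.int64))
    r1 = m1 + u1
    n_meth = m1 + m2
    total = r1 + m2 + u2
    kmax = np.minimum(r1, n_meth)
    kmin = np.maximum(0, n_meth - (total - r1))
    width = int((kmax - kmin).max()) + 1 if m1.size else 1
    ks = kmin[:, None] + np.arange(width)[None, :]
    valid = ks <= kmax[:, None]
    ks_c = np.where(valid, ks, kmin[:, None])
    pmf = stats.hypergeom.pmf(ks_c, total[:, None], n_meth[:, None], r1[:, None])
    pmf = np.where(valid, pmf, 0.0)
    obs = stats.hypergeom.pmf(m1, total, n_meth, r1)
    p = np.sum(np.where(pmf <= obs[:, None] * (1 + _TIE_EPS), pmf, 0.0), axis=1)
    return np.minimum(p, 1.0)


def lrt_two_group(
    meth1: np.ndarray, cov1: np.ndarray, meth2: np.ndarray, cov2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form binomial-logistic LRT of a two-group effect, vectorized.

    Inputs are per-group totals (methylated, coverage) per site; with a single
    binary covariate the GLM fit equals the pooled group proportions, so
    G = 2*(ll_group - ll_null) and p = chi2.sf(G, 1).
    Returns (statistic, pvalue); sites where either group has zero total
    coverage get NaN p (untestable).
    """
    meth1 = np.asarray(meth1, dtype=float)
    cov1 = np.asarray(cov1, dtype=float)
    meth2 = np.asarray(meth2, dtype=float)
    cov2 = np.asarray(cov2, dtype=float)

    def ll(m, c, p):
        return xlogy(m, p) + xlogy(c - m, 1.0 - p)

    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(cov1 > 0, meth1 / np.maximum(cov1, 1e-300), np.nan)
        p2 = np.where(cov2 > 0, meth2 / np.maximum(cov2, 1e-300), np.nan)
        p0 = (meth1 + meth2) / np.maximum(cov1 + cov2, 1e-300)
        g = 2.0 * (ll(meth1, cov1, p1) + ll(meth2, cov2, p2) - ll(meth1, cov1, p0) - ll(meth2, cov2, p0))
    g = np.maximum(g, 0.0)
    untestable = (cov1 <= 0) | (cov2 <= 0)
    pval = stats.chi2.sf(g, df=1)
    pval = np.where(untestable, np.nan, pval)
    g = np.where(untestable, np.nan, g)
    return g, pval


def test_site(
    meth_counts: list[tuple[int, int]], groups: list[str], pool_replicates: bool = False
) -> float:
    """p-value for a single CpG site.

    ``meth_counts`` is per-sample (methylated, coverage), ``groups`` the
    per-sample group labels (exactly two distinct).  Fisher on the pooled
    table when each group has one sample or ``pool_replicates``; otherwise
    the logistic LRT.  NaN when a group has zero total coverage.
    """
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ConfigurationError(f"need exactly 2 groups, got {labels}")
    g1, g2 = labels
    m = np.array([mc[0] for mc in meth_counts], dtype=float)
    c = np.array([mc[1] for mc in meth_counts], dtype=float)
    in1 = np.array([g == g1 for g in groups])
    n1, n2 = int(in1.sum()), int((~in1).sum())
    m1, c1 = m[in1].sum(), c[in1].sum()
    m2, c2 = m[~in1].sum(), c[~in1].sum()
    if c1 <= 0 or c2 <= 0:
        return float("nan")
    if pool_replicates or (n1 == 1 and n2 == 1):
        return float(
            fisher_exact_two_sided(
                np.array([int(m1)]), np.array([int(c1 - m1)]),
                np.array([int(m2)]), np.array([int(c2 - m2)]),
            )[0]
        )
    _, p = lrt_two_group(np.array([m1]), np.array([c1]), np.array([m2]), np.array([c2]))
    return float(p[0])


def adjust_pvalues(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise DataError("p-value outside [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# DMS calling
# ---------------------------------------------------------------------------

def call_dms(
    table: MethylationTable,
    group1: str,
    group2: str,
    min_diff: float = 25.0,
    max_q: float = 0.01,
    pool_replicates: bool = False,
) -> pd.DataFrame:
    """Per-site differential methylation records for group1 vs group2.

    Returns a DataFrame with one row per testable site: chrom, pos, strand,
    mean_pct_group1, mean_pct_group2, meth_diff (percentage points,
    group1 - group2), pvalue, qvalue, direction in {hyper, hypo, ns}.
    Sites untestable (zero group coverage) are excluded.
    """
    for g in (group1, group2):
        if not table.samples_in_group(g):
            raise ConfigurationError(f"group {g!r} has no samples in table")
    s1 = table.samples_in_group(group1)
    s2 = table.samples_in_group(group2)
    cov1 = table.coverage[s1].to_numpy(dtype=float)
    cov2 = table.coverage[s2].to_numpy(dtype=float)
    meth1 = table.methylated[s1].to_numpy(dtype=float)
    meth2 = table.methylated[s2].to_numpy(dtype=float)

    with np.errstate(invalid="ignore", divide="ignore"):
        pct1 = np.where(cov1 > 0, 100.0 * meth1 / np.maximum(cov1, 1e-300), np.nan)
        pct2 = np.where(cov2 > 0, 100.0 * meth2 / np.maximum(cov2, 1e-300), np.nan)
    mean1 = np.nanmean(pct1, axis=1)
    mean2 = np.nanmean(pct2, axis=1)

    M1, C1 = meth1.sum(axis=1), cov1.sum(axis=1)
    M2, C2 = meth2.sum(axis=1), cov2.sum(axis=1)
    if pool_replicates or (len(s1) == 1 and len(s2) == 1):
        testable = (C1 > 0) & (C2 > 0)
        pval = np.full(len(M1), np.nan)
        if testable.any():
            pval[testable] = fisher_exact_two_sided(
                M1[testable].astype(np.int64),
                (C1 - M1)[testable].astype(np.int64),
                M2[testable].astype(np.int64),
                (C2 - M2)[testable].astype(np.int64),
            )
    else:
        _, pval = lrt_two_group(M1, C1, M2, C2)
        testable = ~np.isnan(pval)

    n_untestable = int((~testable).sum())
    if n_untestable:
        log.info("%d sites untestable (zero group coverage), excluded", n_untestable)

    qval = adjust_pvalues(pval)
    diff = mean1 - mean2
    direction = np.where(
        (qval < max_q) & (diff >= min_diff),
        HYPER,
        np.where((qval < max_q) & (diff <= -min_diff), HYPO, NS),
    )
    out = pd.DataFrame(
        {
            "chrom": table.sites["chrom"].to_numpy(),
            "pos": table.sites["pos"].to_numpy(),
            "strand": table.sites["strand"].to_numpy(),
            "mean_pct_group1": mean1,
            "mean_pct_group2": mean2,
            "meth_diff": diff,
            "pvalue": pval,
            "qvalue": qval,
            "direction": direction,
        }
    )
    return out.loc[testable].reset_index(drop=True)


def dms_summary(records: pd.DataFrame) -> dict:
    """Hyper/hypo counts and fractions among called DMSs."""
    called = records[records["direction"].isin([HYPER, HYPO])]
    n = len(called)
    n_hyper = int((called["direction"] == HYPER).sum())
    n_hypo = n - n_hyper
    return {
        "n_tested": int(len(records)),
        "n_dms": n,
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "frac_hyper": n_hyper / n if n else float("nan"),
        "frac_hypo": n_hypo / n if n else float("nan"),
    }


def profile_correlation(table: MethylationTable) -> pd.DataFrame:
    """Pairwise Pearson correlation of percent-methylation profiles.

    Each pair uses the sites covered in both samples; pairs sharing fewer
    than 2 sites get NaN.  The matrix is symmetric with unit diagonal.
    """
    if len(table.sample_ids) < 2:
        raise ConfigurationError("need >= 2 samples for a profile correlation")
    pct = table.percent_methylation().to_numpy()
    samples = table.sample_ids
    n = len(samples)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(pct[:, i]) & ~np.isnan(pct[:, j])
            if both.sum() < 2:
                r = np.nan
            else:
                x, y = pct[both, i], pct[both, j]
                if np.std(x) == 0 or np.std(y) == 0:
                    r = np.nan
                else:
                    r = float(np.corrcoef(x, y)[0, 1])
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=samples, columns=samples)


def feature_distribution(dms: pd.DataFrame, index: RegionIndex) -> dict[str, float]:
    """Fraction of DMSs falling in each feature class.

    Classes are promoter / exon / intron / intergenic.  A DMS is counted once
    per class it touches (exon beats intron within one gene; different genes
    may contribute different classes for the same site), so fractions can sum
    to more than 1 when genes overlap.
    """
    counts = {PROMOTER: 0, EXON: 0, INTRON: 0, INTERGENIC: 0}
    total = len(dms)
    for chrom, pos in zip(dms["chrom"], dms["pos"]):
        hits = index.assign(str(chrom), int(pos))
        if not hits:
            counts[INTERGENIC] += 1
            continue
        per_gene: dict[str, set[str]] = {}
        for gene_id, region in hits:
            per_gene.setdefault(gene_id, set()).add(region)
        classes = set()
        for regions in per_gene.values():
            if PROMOTER in regions:
                classes.add(PROMOTER)
            if EXON in regions:
                classes.add(EXON)
            elif INTRON in regions:
                classes.add(INTRON)
        for cls in classes:
            counts[cls] += 1
    if total == 0:
        return {k: float("nan") for k in counts}
    return {k: v / total for k, v in counts.items()}
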