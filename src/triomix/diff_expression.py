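"""Negative-binomial differential expression for mRNA and miRNA count tables.

A deliberately transparent NB pipeline: median-of-ratios size factors,
method-of-moments per-feature dispersion from within-group pooled variances,
a Wald test on the moderated log2 fold change with a delta-method standard
error, and Benjamini-Hochberg adjustment.  No fold-change shrinkage and no
outlier refitting -- every number is traceable to a formula.  A feature is
differentially expressed (DE) when padj < 0.05 and |log2FC| >= 1.

Expression tiers follow a quartile scheme over mean normalized counts:
Q1 = lowest quartile (low expression), Q3 = highest quartile (high), and
Q2 = the interquartile half between them (medium).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diff_methylation import adjust_pvalues
from .io_formats import ConfigurationError, CountTable, DataError

__all__ = [
    "size_factors",
    "normalized_counts",
    "estimate_dispersion",
    "test_de",
    "assign_tiers",
    "TIER_LOW",
    "TIER_MID",
    "TIER_HIGH",
]

log = logging.getLogger(__name__)

ALPHA_FLOOR = 1e-8
TIER_LOW = "Q1"
TIER_MID = "Q2"
TIER_HIGH = "Q3"
TIER_UNSET = "unset"


def size_factors(counts: CountTable | pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample size factors.

    factor_j = median over features of count_ij / geometric_mean_i, using
    the features with strictly positive counts in every sample; if no such
    feature exists, the median falls back to each sample's positive subset.
    """
    mat = counts.counts if isinstance(counts, CountTable) else counts
    arr = mat.to_numpy(dtype=float)
    if arr.shape[1] == 1:
        return pd.Series([1.0], index=mat.columns)
    all_pos = (arr > 0).all(axis=1)
    if all_pos.any():
        logg = np.log(arr[all_pos])
        geo = logg.mean(axis=1, keepdims=True)
        factors = np.exp(np.median(logg - geo, axis=0))
    else:
        log.warning("no feature positive in all samples; size factors from positive subsets")
        factors = np.empty(arr.shape[1])
        with np.errstate(divide="ignore"):
            logg = np.log(arr)
        geo = np.where((arr > 0), logg, np.nan).mean(axis=1, keepdims=True)
        for j in range(arr.shape[1]):
            ratios = logg[:, j] - geo[:, 0]
            ratios = ratios[np.isfinite(ratios)]
            if ratios.size == 0:
                raise DataError(f"sample {mat.columns[j]!r}: no usable features for size factor")
            factors[j] = np.exp(np.median(ratios))
    return pd.Series(factors, index=mat.columns)


def normalized_counts(counts: CountTable) -> pd.DataFrame:
    sf = size_factors(counts)
    return counts.counts / sf


def estimate_dispersion(norm: pd.DataFrame, groups: dict[str, str]) -> pd.Series:
    """Method-of-moments NB dispersion per feature.

    alpha = max(floor, (s^2 - mu) / mu^2) where s^2 pools the within-group
    variances of normalized counts (df-weighted) and mu is the grand mean.
    Features with zero mean get NaN (untestable).
    """
    if norm.shape[1] < 2:
        raise ConfigurationError("need >= 2 samples to estimate dispersion")
    labels = sorted(set(groups[s] for s in norm.columns))
    mu = norm.mean(axis=1).to_numpy()
    ss = np.zeros(len(norm))
    df = 0
    for g in labels:
        cols = [s for s in norm.columns if groups[s] == g]
        if len(cols) < 2:
            continue
        sub = norm[cols].to_numpy()
        ss += sub.var(axis=1, ddof=1) * (len(cols) - 1)
        df += len(cols) - 1
    if df == 0:  # no replicated group: fall back to overall variance
        s2 = norm.to_numpy().var(axis=1, ddof=1)
    else:
        s2 = ss / df
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = (s2 - mu) / np.maximum(mu, 1e-300) ** 2
    alpha = np.maximum(alpha, ALPHA_FLOOR)
    alpha = np.where(mu > 0, alpha, np.nan)
    return pd.Series(alpha, index=norm.index)


def test_de(
    counts: CountTable,
    group1: str,
    group2: str,
    padj_cutoff: float = 0.05,
    min_abs_lfc: float = 1.0,
    alpha_floor: float = ALPHA_FLOOR,
) -> pd.DataFrame:
    """NB Wald differential expression of group1 vs group2.

    Per feature: log2fc = log2((m1 + 0.5)/(m2 + 0.5)) of normalized group
    means; SE from the NB variance mu + alpha*mu^2 of each sample propagated
    through the group means and the log (delta method); two-sided normal p;
    BH padj.  Returns a DataFrame indexed by feature with columns base_mean,
    log2fc, lfc_se, pvalue, padj, is_de.
    """
    for g in (group1, group2):
        if not counts.samples_in_group(g):
            raise ConfigurationError(f"group {g!r} has no samples in count table")
    sf = size_factors(counts)
    norm = counts.counts / sf
    s1 = counts.samples_in_group(group1)
    s2 = counts.samples_in_group(group2)
    sub_groups = {s: counts.group_of[s] for s in s1 + s2}
    alpha = estimate_dispersion(norm[s1 + s2], sub_groups).to_numpy()
    alpha = np.maximum(alpha, alpha_floor)

    m1 = norm[s1].mean(axis=1).to_numpy()
    m2 = norm[s2].mean(axis=1).to_numpy()
    base_mean = norm[s1 + s2].mean(axis=1).to_numpy()
    lfc = np.log2(m1 + 0.5) - np.log2(m2 + 0.5)

    def group_mean_var(m, cols):
        # Var(mean_j K_ij / s_j) with Var(K_ij) = s_j m + alpha (s_j m)^2
        sj = sf[cols].to_numpy()
        var_terms = (m[:, None] / sj[None, :]) + alpha[:, None] * m[:, None] ** 2
        return var_terms.sum(axis=1) / len(cols) ** 2

    v1 = group_mean_var(m1, s1)
    v2 = group_mean_var(m2, s2)
    ln2 = np.log(2.0)
    se = np.sqrt(v1 / (m1 + 0.5) ** 2 + v2 / (m2 + 0.5) ** 2) / ln2
    testable = np.isfinite(se) & (se > 0) & (base_mean > 0)
    z = np.where(testable, lfc / np.where(se > 0, se, 1.0), np.nan)
    pval = np.where(testable, 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    padj = adjust_pvalues(pval)
    is_de = (padj < padj_cutoff) & (np.abs(lfc) >= min_abs_lfc)
    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": lfc,
            "lfc_se": se,
            "pvalue": pval,
            "padj": padj,
            "is_de": np.where(np.isnan(padj), False, is_de),
        },
        index=counts.counts.index,
    )
    out.index.name = "feature_id"
    return out


def assign_tiers(records: pd.DataFrame, scheme: str = "quartile") -> pd.DataFrame:
    """Attach expression tiers by quartiles of base_mean.

    Features are ranked by (base_mean, feature_id); with k = floor(n/4),
    the k lowest are Q1 (low), the k highest Q3 (high), the rest Q2 (medium).
    Fewer than 4 features leaves every tier unset.
    """
    if scheme != "quartile":
        raise ValueError(f"unknown tier scheme {scheme!r}")
    out = records.copy()
    n = len(out)
    if n < 4:
        log.warning("fewer than 4 features; tiers left unset")
        out["tier"] = TIER_UNSET
        return out
    order = out.assign(_fid=out.index.astype(str)).sort_values(
        ["base_mean", "_fid"], kind="mergesort"
    )
    k = n // 4
    tiers = np.full(n, TIER_MID, dtype=object)
    tiers[:k] = TIER_LOW
    tiers[n - k :] = TIER_HIGH
    out.loc[order.index, "tier"] = tiers
    return out
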