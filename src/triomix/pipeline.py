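"""End-to-end orchestration: simulate or load, run every stage, write reports.

The pipeline is a pure function of (inputs, config, seed): stage order is
fixed, all outputs are sorted before writing, and the manifest carries no
timestamps, so identical runs produce byte-identical output trees.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import RegionIndex, load_gene_models
from .diff_expression import assign_tiers, normalized_counts, test_de
from .diff_methylation import (
    call_dms,
    dms_summary,
    feature_distribution,
    filter_coverage,
)
from .integration import (
    build_pairs,
    cross_comparison_sets,
    select_methylation_dependent,
    stratum_table,
)
from .io_formats import (
    ConfigurationError,
    CountTable,
    MethylationTable,
    TargetMap,
    read_count_table,
    read_methylation_table,
    read_target_map,
    write_bed,
)
from .mirna import build_chains, correlate_pairs, mirna_promoter_dms, predict_targets_seed
from .simulate import SimulatedDataset, SimulationConfig, simulate_dataset, write_dataset

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "evaluate_against_truth"]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "min_diff": 25.0,
    "max_q": 0.01,
    "padj": 0.05,
    "min_lfc": 1.0,
    "target_r": -0.9,
    "min_cov": 10,
    "max_cov_pctile": 99.9,
}


@dataclass
class PipelineConfig:
    """Validated run configuration (YAML-backed)."""

    output_dir: Path
    comparisons: list[dict]
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    thresholds: dict = field(default_factory=dict)
    tss_window: int = 1500
    pool_replicates: bool = False

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        self.thresholds = {**DEFAULT_THRESHOLDS, **self.thresholds}
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError("config needs exactly one of 'simulate' or 'inputs'")
        if not self.comparisons:
            raise ConfigurationError("no comparisons configured")
        for cmp in self.comparisons:
            for key in ("name", "group1", "group2"):
                if key not in cmp:
                    raise ConfigurationError(f"comparison missing {key!r}")
        t = self.thresholds
        if not (0 < t["max_q"] <= 1 and 0 < t["padj"] <= 1):
            raise ConfigurationError("q/padj thresholds must lie in (0, 1]")
        if not (0 < t["min_diff"] <= 100):
            raise ConfigurationError("min_diff must lie in (0, 100]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            output_dir=raw.get("output_dir", "triomix_run"),
            comparisons=raw.get("comparisons", []),
            seed=int(raw.get("seed", 0)),
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            thresholds=raw.get("thresholds", {}) or {},
            tss_window=int(raw.get("tss_window", 1500)),
            pool_replicates=bool(raw.get("pool_replicates", False)),
        )


@dataclass
class ComparisonResult:
    name: str
    dms: pd.DataFrame
    dms_summary: dict
    feature_dist: dict
    gene_de: pd.DataFrame
    mirna_de: pd.DataFrame
    pairs: pd.DataFrame
    strata: pd.DataFrame
    meth_dependent: dict[str, pd.DataFrame]
    target_pairs: pd.DataFrame
    chains: list


@dataclass
class PipelineResult:
    config: PipelineConfig
    comparisons: dict[str, ComparisonResult]
    cross_patterns: pd.DataFrame | None
    dataset: SimulatedDataset | None  # set when inputs were simulated
    manifest: dict


def _load_inputs(config: PipelineConfig):
    """Return (models, meth_table, gene_counts, mirna_counts, target_map or seqs, dataset)."""
    if config.simulate is not None:
        sim_cfg = SimulationConfig(seed=config.seed, **{
            k: v for k, v in config.simulate.items() if k != "seed"
        })
        ds = simulate_dataset(sim_cfg)
        return ds.models, ds.methylation, ds.gene_counts, ds.mirna_counts, {
            "mirna_seqs": ds.mirna_seqs, "utr_seqs": ds.utr_seqs
        }, ds
    inp = config.inputs
    sheet = pd.read_csv(inp["sample_sheet"], sep="\t")
    sample_sheet = dict(zip(sheet["sample"].astype(str), sheet["group"].astype(str)))
    models = load_gene_models(inp["gtf"])
    meth = read_methylation_table(inp["methylation"], sample_sheet)
    genes = read_count_table(inp["gene_counts"], sample_sheet)
    mirnas = read_count_table(inp["mirna_counts"], sample_sheet)
    if "target_map" in inp:
        targets = {"target_map": read_target_map(inp["target_map"])}
    elif "mirna_fasta" in inp and "utr_fasta" in inp:
        targets = {
            "mirna_seqs": _read_fasta(inp["mirna_fasta"]),
            "utr_seqs": _read_fasta(inp["utr_fasta"]),
        }
    else:
        targets = {"target_map": TargetMap()}
    return models, meth, genes, mirnas, targets, None


def _read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _write_tsv(df: pd.DataFrame, path: Path, sort_by: list[str] | None = None) -> int:
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return len(df)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage for every configured comparison.

    Writes, per comparison, under <output_dir>/<name>/: dms.tsv, dms.bed,
    feature_distribution.tsv, de_mrna.tsv, de_mirna.tsv, stratum_table.tsv,
    meth_dependent_promoter.tsv, meth_dependent_gene_body.tsv,
    mirna_target_pairs.tsv, chains.tsv; plus cross_comparison_patterns.tsv
    and manifest.json at the top level.
    """
    t = config.thresholds
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    models, meth_raw, gene_counts, mirna_counts, targets, dataset = _load_inputs(config)
    if dataset is not None:
        write_dataset(dataset, outdir / "simulated_inputs")

    index = RegionIndex(models, tss_window=config.tss_window)
    mirna_ids = {m.gene_id for m in models if m.biotype == "miRNA"}
    meth = filter_coverage(meth_raw, min_cov=int(t["min_cov"]), max_pctile=t["max_cov_pctile"])
    gene_norm = normalized_counts(gene_counts)
    mirna_norm = normalized_counts(mirna_counts)

    if "target_map" in targets:
        target_map = targets["target_map"]
    else:
        target_map = predict_targets_seed(targets["mirna_seqs"], targets["utr_seqs"])

    counts: dict[str, int] = {}
    results: dict[str, ComparisonResult] = {}
    for cmp in config.comparisons:
        name, g1, g2 = cmp["name"], cmp["group1"], cmp["group2"]
        cdir = outdir / name
        cdir.mkdir(exist_ok=True)
        try:
            res = _run_comparison(
                name, g1, g2, meth, gene_counts, gene_norm, mirna_counts, mirna_norm,
                index, mirna_ids, target_map, t, config.pool_replicates,
            )
        except Exception as exc:  # annotate failures with the stage context
            raise RuntimeError(f"comparison {name!r} failed: {exc}") from exc
        results[name] = res
        counts[f"{name}/dms"] = _write_tsv(res.dms, cdir / "dms.tsv", ["chrom", "pos", "strand"])
        called = res.dms[res.dms["direction"] != "ns"]
        write_bed(
            (
                {"chrom": r["chrom"], "pos": r["pos"], "strand": r["strand"],
                 "name": r["direction"], "score": float(r["meth_diff"])}
                for _, r in called.iterrows()
            ),
            cdir / "dms.bed",
        )
        counts[f"{name}/dms_called"] = len(called)
        pd.DataFrame([res.feature_dist]).to_csv(
            cdir / "feature_distribution.tsv", sep="\t", index=False, float_format="%.6g"
        )
        counts[f"{name}/de_mrna"] = _write_tsv(
            res.gene_de.reset_index(), cdir / "de_mrna.tsv", ["feature_id"]
        )
        counts[f"{name}/de_mirna"] = _write_tsv(
            res.mirna_de.reset_index(), cdir / "de_mirna.tsv", ["feature_id"]
        )
        counts[f"{name}/pairs"] = _write_tsv(
            res.pairs, cdir / "site_gene_pairs.tsv", ["chrom", "pos", "gene_id", "region"]
        )
        counts[f"{name}/strata"] = _write_tsv(res.strata, cdir / "stratum_table.tsv")
        for cls, df in res.meth_dependent.items():
            counts[f"{name}/meth_dependent_{cls}"] = _write_tsv(
                df, cdir / f"meth_dependent_{cls}.tsv", ["gene_id"]
            )
        counts[f"{name}/target_pairs"] = _write_tsv(
            res.target_pairs, cdir / "mirna_target_pairs.tsv", ["mirna_id", "gene_id"]
        )
        chain_rows = [row for ch in res.chains for row in ch.to_rows()]
        chain_df = pd.DataFrame(
            chain_rows,
            columns=["mirna_id", "promoter_dms", "n_promoter_dms", "mirna_log2fc",
                     "mirna_padj", "meth_mirna_r", "meth_mirna_p", "gene_id",
                     "target_r", "target_p", "gene_log2fc", "passes_cutoff"],
        )
        counts[f"{name}/chains"] = _write_tsv(chain_df, cdir / "chains.tsv", ["mirna_id", "gene_id"])
        with open(cdir / "dms_summary.json", "w") as fh:
            json.dump(res.dms_summary, fh, sort_keys=True, indent=2)
            fh.write("\n")

    cross = None
    if len(config.comparisons) >= 2:
        gene_lists = {
            name: dict(zip(res.meth_dependent["promoter"]["gene_id"],
                           res.meth_dependent["promoter"]["label"]))
            for name, res in results.items()
        }
        cross = cross_comparison_sets(gene_lists)
        counts["cross_comparison_patterns"] = _write_tsv(
            cross, outdir / "cross_comparison_patterns.tsv", ["gene_id"]
        )

    manifest = {
        "triomix_version": __version__,
        "seed": config.seed,
        "thresholds": {k: float(v) for k, v in t.items()},
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "comparisons": config.comparisons,
                    "simulate": config.simulate,
                    "inputs": {k: str(v) for k, v in (config.inputs or {}).items()},
                    "thresholds": {k: float(v) for k, v in t.items()},
                    "tss_window": config.tss_window,
                    "seed": config.seed,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "row_counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return PipelineResult(
        config=config, comparisons=results, cross_patterns=cross, dataset=dataset,
        manifest=manifest,
    )


def _run_comparison(
    name, g1, g2, meth, gene_counts, gene_norm, mirna_counts, mirna_norm,
    index, mirna_ids, target_map, t, pool_replicates,
) -> ComparisonResult:
    dms = call_dms(
        meth, g1, g2, min_diff=t["min_diff"], max_q=t["max_q"], pool_replicates=pool_replicates
    )
    summary = dms_summary(dms)
    called = dms[dms["direction"] != "ns"]
    fdist = feature_distribution(called, index)

    gene_de = test_de(gene_counts, g1, g2, padj_cutoff=t["padj"], min_abs_lfc=t["min_lfc"])
    gene_de = assign_tiers(gene_de)
    mirna_de = test_de(mirna_counts, g1, g2, padj_cutoff=t["padj"], min_abs_lfc=t["min_lfc"])

    s1 = gene_counts.samples_in_group(g1)
    s2 = gene_counts.samples_in_group(g2)
    pairs = build_pairs(dms, index, gene_de, gene_norm, s1, s2)
    strata = stratum_table(pairs)
    meth_dep = select_methylation_dependent(pairs, max_padj=t["padj"], min_abs_lfc=t["min_lfc"])

    samples = s1 + s2
    target_pairs = correlate_pairs(
        target_map, mirna_norm, gene_norm, gene_de, samples, r_cutoff=t["target_r"]
    )
    prom_map = mirna_promoter_dms(index, dms, mirna_ids)
    chains = build_chains(
        prom_map, mirna_de, target_pairs, meth, mirna_norm, gene_de, samples,
        r_cutoff=t["target_r"],
    )
    return ComparisonResult(
        name=name, dms=dms, dms_summary=summary, feature_dist=fdist, gene_de=gene_de,
        mirna_de=mirna_de, pairs=pairs, strata=strata, meth_dependent=meth_dep,
        target_pairs=target_pairs, chains=chains,
    )


# ---------------------------------------------------------------------------
# truth evaluation
# ---------------------------------------------------------------------------

def _sens_fdr(called: set, planted: set) -> dict:
    tp = len(called & planted)
    fp = len(called - planted)
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "sensitivity": tp / len(planted) if planted else float("nan"),
        "fdr": fp / len(called) if called else 0.0,
    }


def evaluate_against_truth(result: PipelineResult, comparison: str | None = None) -> dict:
    """Sensitivity and empirical FDR per planted effect class.

    Requires a pipeline run with simulated inputs (the truth is attached to
    the run's dataset).  Classes: DMS sites, DE genes, DE miRNAs, promoter-
    coupled genes, miRNA-target pairs, cascade chains.
    """
    if result.dataset is None:
        raise ConfigurationError("truth evaluation needs a simulated run")
    truth = result.dataset.truth
    if comparison is None:
        comparison = next(iter(result.comparisons))
    res = result.comparisons[comparison]

    called_dms = {
        (r["chrom"], int(r["pos"]), r["strand"])
        for _, r in res.dms.iterrows()
        if r["direction"] != "ns"
    }
    planted_dms = {
        (r["chrom"], int(r["pos"]), r["strand"]) for _, r in truth.dms.iterrows()
    }
    tested_dms = {
        (r["chrom"], int(r["pos"]), r["strand"]) for _, r in res.dms.iterrows()
    }
    called_deg = set(res.gene_de.index[res.gene_de["is_de"]])
    planted_deg = {
        g for g, lfc in zip(truth.de_genes["gene_id"], truth.de_genes["log2fc"])
        if abs(lfc) >= 1
    }
    called_demir = set(res.mirna_de.index[res.mirna_de["is_de"]])
    planted_demir = set(truth.de_mirnas["mirna_id"])
    called_prom = set(res.meth_dependent["promoter"]["gene_id"])
    planted_prom = set(truth.coupled_genes["gene_id"])
    called_pairs = {
        (r["mirna_id"], r["gene_id"])
        for _, r in res.target_pairs.iterrows()
        if r["retained"]
    }
    planted_pairs = set(map(tuple, truth.mirna_targets.to_numpy()))
    called_chains = {c.mirna_id for c in res.chains}
    planted_chains = set(truth.cascades["mirna_id"])

    # sensitivity is reported over planted sites that survived coverage
    # filtering (the test cannot recover a site it never saw); the unfiltered
    # total is reported alongside
    dms_report = _sens_fdr(called_dms, planted_dms & tested_dms)
    dms_report["n_planted_total"] = len(planted_dms)
    dms_report["fdr"] = (
        len(called_dms - planted_dms) / len(called_dms) if called_dms else 0.0
    )
    report = {
        "comparison": comparison,
        "dms": dms_report,
        "deg": _sens_fdr(called_deg, planted_deg),
        "de_mirna": _sens_fdr(called_demir, planted_demir),
        "promoter_coupled": _sens_fdr(called_prom, planted_prom),
        "mirna_target": _sens_fdr(called_pairs, planted_pairs),
        "chains": {
            **_sens_fdr(called_chains, planted_chains),
            "n_target_links": {
                c.mirna_id: int(len(c.target_links)) for c in res.chains
            },
        },
    }
    return report
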