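"""Readers and writers for every external table the pipeline touches.

All parsers are strict: a malformed row raises instead of being dropped,
so that upstream data problems surface at load time rather than as silently
shrunken result tables.

Coordinate convention: CpG positions are 1-based internally (matching the
Bismark-coverage style the methylation TSV dialect mimics); BED output is
the single place where 0-based half-open coordinates are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "ConfigurationError",
    "MethylationTable",
    "CountTable",
    "TargetMap",
    "read_methylation_table",
    "write_methylation_table",
    "read_count_table",
    "write_count_table",
    "read_target_map",
    "write_target_map",
    "write_bed",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(ValueError):
    """Inconsistency between data and run configuration (sample sheets, groups)."""


SITE_COLUMNS = ("chrom", "pos", "strand")


@dataclass
class MethylationTable:
    """Per-CpG (coverage, methylated) counts across named, grouped samples.

    ``sites`` holds one row per CpG with columns chrom, pos (1-based cytosine
    position), strand; ``coverage`` and ``methylated`` are aligned integer
    frames with one column per sample.
    """

    sites: pd.DataFrame
    coverage: pd.DataFrame
    methylated: pd.DataFrame
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coverage.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> pd.Index:
        s = self.sites
        return pd.Index(
            s["chrom"].astype(str) + ":" + s["pos"].astype(str) + ":" + s["strand"].astype(str)
        )

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def percent_methylation(self) -> pd.DataFrame:
        """Per-site percent methylation per sample; NaN where coverage is 0."""
        cov = self.coverage.to_numpy(dtype=float)
        meth = self.methylated.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(cov > 0, 100.0 * meth / cov, np.nan)
        return pd.DataFrame(pct, columns=self.sample_ids, index=self.coverage.index)

    def subset_sites(self, mask: np.ndarray | pd.Series) -> "MethylationTable":
        mask = np.asarray(mask, dtype=bool)
        return MethylationTable(
            sites=self.sites.loc[mask].reset_index(drop=True),
            coverage=self.coverage.loc[mask].reset_index(drop=True),
            methylated=self.methylated.loc[mask].reset_index(drop=True),
            group_of=dict(self.group_of),
        )

    def validate(self) -> None:
        if list(self.coverage.columns) != list(self.methylated.columns):
            raise DataError("coverage and methylated sample columns differ")
        if not (len(self.sites) == len(self.coverage) == len(self.methylated)):
            raise DataError("site/coverage/methylated row counts differ")
        if len(set(self.coverage.columns)) != len(self.coverage.columns):
            raise DataError("duplicate sample ids")
        missing = [s for s in self.coverage.columns if s not in self.group_of]
        if missing:
            raise ConfigurationError(f"samples missing from sample sheet: {missing}")
        cov = self.coverage.to_numpy()
        meth = self.methylated.to_numpy()
        if (cov < 0).any() or (meth < 0).any():
            raise DataError("negative coverage or methylated count")
        bad = np.argwhere(meth > cov)
        if bad.size:
            i, j = bad[0]
            row = self.sites.iloc[i]
            raise DataError(
                f"methylated > coverage at {row['chrom']}:{row['pos']} "
                f"sample {self.coverage.columns[j]}"
            )
        dup = self.sites.duplicated(subset=list(SITE_COLUMNS))
        if dup.any():
            row = self.sites.loc[dup.idxmax()]
            raise DataError(f"duplicate site {row['chrom']}:{row['pos']}:{row['strand']}")
        bad_strand = ~self.sites["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise DataError(f"invalid strand value {self.sites.loc[bad_strand.idxmax(), 'strand']!r}")


@dataclass
class CountTable:
    """Feature x sample raw count matrix with per-sample group labels."""

    counts: pd.DataFrame  # features x samples, integer
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise DataError(f"duplicate feature id {dup!r}")
        if len(set(self.counts.columns)) != len(self.counts.columns):
            raise DataError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise DataError("negative count")
        missing = [s for s in self.counts.columns if s not in self.group_of]
        if missing:
            raise ConfigurationError(f"samples missing from sample sheet: {missing}")


@dataclass
class TargetMap:
    """Unique (mirna_id, gene_id) pairs with their provenance."""

    pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["mirna_id", "gene_id", "source"])
    )

    def __post_init__(self) -> None:
        if self.pairs.duplicated(subset=["mirna_id", "gene_id"]).any():
            raise DataError("duplicate (mirna, gene) pair in target map")

    def targets_of(self, mirna_id: str) -> list[str]:
        p = self.pairs
        return sorted(p.loc[p["mirna_id"] == mirna_id, "gene_id"])

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# methylation TSV dialect:
#   chrom  pos  strand  <sample>_coverage  <sample>_methylated  ...
# ---------------------------------------------------------------------------

def read_methylation_table(path: str | Path, sample_sheet: Mapping[str, str]) -> MethylationTable:
    """Read the per-CpG methylation-call TSV and validate it.

    ``sample_sheet`` maps every sample name appearing in the header to its
    tissue-group label; a sample without a label is a configuration error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty methylation file") from None
    for col in SITE_COLUMNS:
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    samples: list[str] = []
    for col in df.columns:
        if col.endswith("_coverage"):
            s = col[: -len("_coverage")]
            if f"{s}_methylated" not in df.columns:
                raise DataError(f"{path}: sample {s!r} has coverage but no methylated column")
            samples.append(s)
    if not samples:
        raise DataError(f"{path}: no sample coverage/methylated column pairs")
    unknown = [s for s in samples if s not in sample_sheet]
    if unknown:
        raise ConfigurationError(f"{path}: samples not in sample sheet: {unknown}")
    cov = df[[f"{s}_coverage" for s in samples]].copy()
    meth = df[[f"{s}_methylated" for s in samples]].copy()
    for frame, kind in ((cov, "coverage"), (meth, "methylated")):
        arr = frame.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            flt = frame.astype(float).to_numpy()
            if np.isnan(flt).any() or (flt != np.round(flt)).any():
                raise DataError(f"{path}: non-integer {kind} value")
    cov.columns = samples
    meth.columns = samples
    return MethylationTable(
        sites=df[list(SITE_COLUMNS)].copy(),
        coverage=cov.astype(np.int64),
        methylated=meth.astype(np.int64),
        group_of={s: sample_sheet[s] for s in samples},
    )


def write_methylation_table(table: MethylationTable, path: str | Path) -> None:
    out = table.sites.copy()
    for s in table.sample_ids:
        out[f"{s}_coverage"] = table.coverage[s].to_numpy()
        out[f"{s}_methylated"] = table.methylated[s].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path, sample_sheet: Mapping[str, str]) -> CountTable:
    """Read a feature x sample integer count TSV (first column = feature id)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty count file") from None
    if df.shape[1] == 0:
        raise DataError(f"{path}: no sample columns")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise DataError(f"{path}: non-numeric count cell")
    flt = arr.astype(float)
    if np.isnan(flt).any() or (flt != np.round(flt)).any():
        raise DataError(f"{path}: non-integer count cell")
    unknown = [s for s in df.columns if s not in sample_sheet]
    if unknown:
        raise ConfigurationError(f"{path}: samples not in sample sheet: {unknown}")
    df.index = df.index.astype(str)
    df.index.name = "feature_id"
    return CountTable(
        counts=df.astype(np.int64),
        group_of={s: sample_sheet[s] for s in df.columns},
    )


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="feature_id")


def read_target_map(path: str | Path) -> TargetMap:
    """Read a miRNA->gene target TSV with columns mirna_id, gene_id [, source]."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty target map") from None
    for col in ("mirna_id", "gene_id"):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    if "source" not in df.columns:
        df["source"] = "user_supplied"
    return TargetMap(pairs=df[["mirna_id", "gene_id", "source"]].reset_index(drop=True))


def write_target_map(tmap: TargetMap, path: str | Path) -> None:
    tmap.pairs.to_csv(path, sep="\t", index=False)


def write_bed(records: Iterable[Mapping], path: str | Path) -> None:
    """Write positioned records as BED6.

    Each record needs chrom, pos (1-based), strand, and optionally name and
    score. Output start/end are 0-based half-open (start = pos-1, end = pos)
    and rows are sorted by (chrom, start, name) so the file is deterministic
    regardless of input order.
    """
    rows = []
    for rec in records:
        pos = int(rec["pos"])
        if pos < 1:
            raise DataError(f"position {pos} < 1 in BED export")
        rows.append(
            (
                str(rec["chrom"]),
                pos - 1,
                pos,
                str(rec.get("name", ".")),
                rec.get("score", 0),
                str(rec.get("strand", ".")),
            )
        )
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            score_s = f"{score:.6g}" if isinstance(score, float) else str(score)
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score_s}\t{strand}\n")
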