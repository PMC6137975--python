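"""Readers and writers for the tabular and BED artifacts.

All tables are tab-separated UTF-8 with a header row; genomic coordinates
are 0-based half-open everywhere (BED-native). Floats are written with 12
significant digits so write-then-read round-trips are exact at that
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from epimem.config import PROBE_CATEGORIES

FLOAT_FORMAT = "%.12g"

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "category", "gene_id"]
SAMPLE_COLUMNS = ["sample_id", "condition", "replicate"]
BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class ParseError(ValueError):
    """Raised when an input file fails validation."""


@dataclass
class SignalMatrix:
    """Per-probe, per-sample normalized signal values plus sample metadata.

    ``values`` is indexed by probe_id with one column per sample_id;
    ``samples`` carries (sample_id, condition, replicate) rows in column
    order of ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ParseError("signal columns and sample metadata disagree")

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    def condition_means(self, condition: str | None = None) -> pd.Series | pd.DataFrame:
        """Per-probe signal averaged across the replicate samples of each condition."""
        by_cond = {
            cond: self.values[group["sample_id"].tolist()].mean(axis=1)
            for cond, group in self.samples.groupby("condition", sort=False)
        }
        if condition is not None:
            return by_cond[condition]
        return pd.DataFrame(by_cond)

    def subset_probes(self, probe_ids) -> "SignalMatrix":
        return SignalMatrix(self.values.loc[list(probe_ids)], self.samples)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_probes(path: str | Path) -> pd.DataFrame:
    """Read and validate a probe annotation table.

    Raises :class:`ParseError` naming the offending line for unknown
    categories, malformed coordinates, or duplicate probe ids.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": "string"})
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    # +2: header line plus 1-based numbering
    for idx, row in df.iterrows():
        line = idx + 2
        if row["category"] not in PROBE_CATEGORIES:
            raise ParseError(f"{path}:{line}: unknown category {row['category']!r}")
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError):
            raise ParseError(f"{path}:{line}: malformed coordinates") from None
        if start < 0 or start >= end:
            raise ParseError(f"{path}:{line}: invalid interval [{start}, {end})")
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if not dup.empty:
        line = dup.index[0] + 2
        raise ParseError(f"{path}:{line}: duplicate probe_id {dup.iloc[0]!r}")
    return df[PROBE_COLUMNS]


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id")
    return df[SAMPLE_COLUMNS]


def read_signals(path: str | Path, samples_path: str | Path,
                 probes: pd.DataFrame | None = None) -> SignalMatrix:
    """Read a probe-by-sample signal matrix, validated against samples.tsv.

    Cells equal to ``NA`` (or empty) become missing values; non-numeric
    cells and sample columns absent from the metadata are errors.
    """
    samples = read_samples(samples_path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if "probe_id" not in df.columns:
        raise ParseError(f"{path}: missing probe_id column")
    df = df.set_index("probe_id")
    declared = set(samples["sample_id"])
    undeclared = [c for c in df.columns if c not in declared]
    if undeclared:
        raise ParseError(f"{path}: sample columns {undeclared} absent from {samples_path}")
    absent = [s for s in samples["sample_id"] if s not in df.columns]
    if absent:
        raise ParseError(f"{path}: declared samples {absent} have no signal column")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ParseError(f"{path}: non-numeric cell {bad.iloc[0]!r} in column {col}")
    if probes is not None:
        unknown = df.index.difference(probes["probe_id"])
        if len(unknown):
            raise ParseError(f"{path}: {len(unknown)} probe ids absent from probe table")
    df = df[list(samples["sample_id"])].astype(float)
    return SignalMatrix(values=df, samples=samples)


def write_signals(matrix: SignalMatrix, path: str | Path) -> None:
    out = matrix.values.reset_index()
    out = out.rename(columns={out.columns[0]: "probe_id"})
    write_tsv(out, path)


def read_genes_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=BED6_COLUMNS)
    return df.rename(columns={"name": "gene_id"})[["chrom", "start", "end", "gene_id", "score", "strand"]]


def write_genes_bed(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.copy()
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    name_col = "gene_id" if "gene_id" in out.columns else "name"
    out[["chrom", "start", "end", name_col, "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False)


def write_windows(results: pd.DataFrame, path: str | Path) -> None:
    """Write the merged per-window result table (both conditions side by side)."""
    write_tsv(results, path)


def read_windows(path: str | Path) -> pd.DataFrame:
    return read_tsv(path)


_BED_SCORE = {"hypo": 0, "hyper": 1000}


def write_dmrs_bed(dmrs, path: str | Path) -> None:
    """BED6 export: name = direction_intensity, score 0/1000 for hypo/hyper."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for d in dmrs:
            score = _BED_SCORE.get(d.direction, 500)
            fh.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.direction}_{d.intensity}\t{score}\t.\n")


def dmrs_to_frame(dmrs) -> pd.DataFrame:
    rows = []
    for d in dmrs:
        rows.append({
            "window_id": d.window_id, "chrom": d.chrom, "start": d.start, "end": d.end,
            "score_favorable": d.score_favorable, "score_unfavorable": d.score_unfavorable,
            "direction": d.direction, "intensity": d.intensity,
            "categories": ";".join(f"{k}:{v}" for k, v in sorted(d.category_counts.items())),
            "genes": ";".join(d.gene_ids),
        })
    return pd.DataFrame(rows, columns=[
        "window_id", "chrom", "start", "end", "score_favorable", "score_unfavorable",
        "direction", "intensity", "categories", "genes"])


def write_dmrs(dmrs, bed_path: str | Path, tsv_path: str | Path) -> None:
    write_dmrs_bed(dmrs, bed_path)
    write_tsv(dmrs_to_frame(dmrs), tsv_path)
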