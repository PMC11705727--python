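"""Readers and writers for the plain-text formats the pipeline consumes.

Conventions
-----------
* Fragments and annotation regions are BED3+ (tab-separated, 0-based
  half-open); lines starting with ``#`` are ignored.
* Per-CpG methylation calls are a 4-column TSV ``chrom, position,
  methylated count, unmethylated count`` with **1-based** positions on disk
  (bismark-coverage dialect); positions are 0-based in memory and converted
  at this boundary only.
* The sample sheet is a TSV with columns ``sample_id, group, split`` and an
  optional ``stage`` column.
* Feature tables are sample x feature TSVs with the sample id as row index,
  accompanied by a JSON sidecar recording which training samples defined
  the features (so train/validation leakage is auditable).

Readers are strict: malformed lines raise a :class:`ParseError` naming the
offending line numbers instead of being silently coerced or skipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_CLASSES = ("nucleosome", "cpg_island", "dnase_cluster", "enhancer")

__all__ = [
    "ParseError",
    "AnnotationRegion",
    "ANNOTATION_CLASSES",
    "read_fragments",
    "write_fragments",
    "read_cpg_calls",
    "write_cpg_calls",
    "read_regions",
    "write_regions",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_feature_table",
    "write_feature_table",
]


class ParseError(ValueError):
    """A file violated its format contract; message lists line numbers."""


@dataclass(frozen=True)
class AnnotationRegion:
    chrom: str
    start: int
    end: int
    class_label: str

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def _read_bed3(path) -> pd.DataFrame:
    rows = []
    errors = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                errors.append(f"line {lineno}: fewer than 3 columns")
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinates {fields[1:3]}")
                continue
            if start < 0:
                errors.append(f"line {lineno}: negative start {start}")
                continue
            if start >= end:
                errors.append(f"line {lineno}: inverted/empty interval [{start}, {end})")
                continue
            rows.append((fields[0], start, end))
    if errors:
        raise ParseError(f"{path}: " + "; ".join(errors))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def read_fragments(path) -> pd.DataFrame:
    """Read aligned cfDNA fragments from a BED3+ file.

    Returns a DataFrame (chrom, start, end) sorted by (chrom, start) with a
    ``length`` column.
    """
    df = _read_bed3(path)
    df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    df["length"] = df["end"] - df["start"]
    return df


def write_fragments(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_cpg_calls(path) -> pd.DataFrame:
    """Read per-CpG methylation calls (chrom, 1-based pos, meth, unmeth).

    Positions are converted to 0-based.  Zero-coverage sites are retained;
    their methylation rate is undefined (NaN in the ``rate`` accessor used
    downstream), never silently zero.
    """
    rows = []
    errors = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                errors.append(f"line {lineno}: fewer than 4 columns")
                continue
            try:
                pos, meth, unmeth = int(fields[1]), int(fields[2]), int(fields[3])
            except ValueError:
                errors.append(f"line {lineno}: non-integer fields {fields[1:4]}")
                continue
            if pos < 1:
                errors.append(f"line {lineno}: position {pos} < 1 (positions are 1-based)")
                continue
            if meth < 0 or unmeth < 0:
                errors.append(f"line {lineno}: negative counts ({meth}, {unmeth})")
                continue
            rows.append((fields[0], pos - 1, meth, unmeth))
    if errors:
        raise ParseError(f"{path}: " + "; ".join(errors))
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])


def write_cpg_calls(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["pos"] = out["pos"] + 1  # back to the 1-based on-disk dialect
    out[["chrom", "pos", "meth", "unmeth"]].to_csv(path, sep="\t", header=False, index=False)


def read_regions(path, class_label: str) -> pd.DataFrame:
    """Read annotation regions (BED3+) and compute integer centers."""
    if class_label not in ANNOTATION_CLASSES:
        raise ValueError(f"unknown annotation class {class_label!r}")
    df = _read_bed3(path)
    df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    df["center"] = (df["start"] + df["end"]) // 2
    df["class_label"] = class_label
    return df


def write_regions(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the sample sheet and validate ids, groups and splits."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ParseError(f"{path}: duplicate sample ids {dups}")
    bad_split = set(df["split"]) - {"train", "validation"}
    if bad_split:
        raise ParseError(f"{path}: unknown split values {sorted(bad_split)}")
    groups = set(df["group"])
    if not (groups <= {"control", "case"} or groups <= {"PDSD", "PRCR"}):
        raise ParseError(f"{path}: group labels must be control/case or PDSD/PRCR, got {sorted(groups)}")
    return df


def write_sample_sheet(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_feature_table(
    table: pd.DataFrame,
    path,
    *,
    omics: str | None = None,
    train_samples: list[str] | None = None,
) -> None:
    """Write a sample x feature TSV plus a JSON provenance sidecar."""
    path = Path(path)
    table.to_csv(path, sep="\t", index_label="sample_id")
    sidecar = {
        "omics": omics,
        "n_samples": int(table.shape[0]),
        "n_features": int(table.shape[1]),
        "feature_names": [str(c) for c in table.columns],
        "train_samples_defining_features": sorted(train_samples) if train_samples else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
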