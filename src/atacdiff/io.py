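"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic coordinates are handled internally as 0-based half-open.  BED
input/output is strictly 0-based half-open; a ``one_based=True`` flag on the
readers/writers converts from/to 1-based fully-closed coordinates for tools
that use that dialect (the shift is applied on read and undone on write, so a
round trip reproduces the original text).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .intervals import INTERVAL_COLUMNS, validate_intervals

REGION_COLUMNS = ["snp_id", "chrom", "pos", "label"]


def read_bed(path, one_based: bool = False) -> pd.DataFrame:
    """Read a 3+ column BED file into an interval table.

    Malformed lines (fewer than 3 fields, non-integer or negative
    coordinates, empty intervals) raise with the 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start coordinate")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            rows.append((chrom, start, end))
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def write_bed(df: pd.DataFrame, path, one_based: bool = False) -> None:
    df = validate_intervals(df)
    out = df[INTERVAL_COLUMNS].copy()
    if one_based:
        out["start"] = out["start"] + 1
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    """Peak-by-sample count matrix; rows indexed by ``chrom:start-end`` ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df.astype("int64")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    counts.to_csv(path, sep="\t", index_label="peak_id")


def read_metadata_csv(path) -> pd.DataFrame:
    """Per-sample metadata table indexed by sample_id."""
    return pd.read_csv(path, index_col="sample_id")


def write_metadata_csv(metadata: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    metadata.to_csv(path, index_label="sample_id")


def read_regions_tsv(path) -> pd.DataFrame:
    """GWAS tag-SNP table with columns snp_id, chrom, pos, label."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["pos"] < 0).any():
        raise ValueError(f"{path}: negative SNP position")
    return df[REGION_COLUMNS + [c for c in df.columns if c not in REGION_COLUMNS]]


def write_regions_tsv(regions: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    regions.to_csv(path, sep="\t", index=False)
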