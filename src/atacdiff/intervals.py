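"""Genomic interval algebra on plain pandas DataFrames.

Intervals are 0-based, half-open ``[start, end)`` with columns
``chrom``, ``start``, ``end``.  Peak identifiers are canonicalized as
``"chrom:start-end"`` in the same convention.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]

_PEAK_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def validate_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and ``start < end``; return a copy with int coords."""
    missing = [c for c in INTERVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interval table is missing columns: {missing}")
    out = df.copy()
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    bad = out.index[(out["end"] <= out["start"]) | (out["start"] < 0)]
    if len(bad):
        rec = out.loc[bad[0]]
        raise ValueError(
            f"malformed interval at index {bad[0]}: "
            f"{rec['chrom']}:{rec['start']}-{rec['end']} (need 0 <= start < end)"
        )
    return out


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def peak_ids(df: pd.DataFrame) -> pd.Index:
    """Canonical ``chrom:start-end`` identifiers."""
    return pd.Index(
        df["chrom"].astype(str) + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)
    )


def intervals_from_ids(ids) -> pd.DataFrame:
    """Parse ``chrom:start-end`` identifiers back into an interval table."""
    rows = []
    for pid in ids:
        m = _PEAK_ID_RE.match(str(pid))
        if m is None:
            raise ValueError(f"cannot parse peak id {pid!r} (expected chrom:start-end)")
        rows.append((m["chrom"], int(m["start"]), int(m["end"])))
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def merge_intervals(df: pd.DataFrame, *, bookended: bool = True) -> pd.DataFrame:
    """Coalesce overlapping (and, by default, bookended) intervals.

    Returns a sorted, disjoint interval set.  ``bookended=True`` merges
    abutting intervals where one ends exactly where the next starts.
    """
    df = sort_intervals(validate_intervals(df))
    if df.empty:
        return df[INTERVAL_COLUMNS]
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            joined = s <= cur_e if bookended else s < cur_e
            if joined:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLUMNS)


def merge_peak_sets(sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of several interval sets, coalescing overlaps and bookends."""
    if not sets:
        return pd.DataFrame(columns=INTERVAL_COLUMNS)
    cat = pd.concat([validate_intervals(s)[INTERVAL_COLUMNS] for s in sets], ignore_index=True)
    return merge_intervals(cat)


_SEX_CHROM_BASES = {"x", "y"}


def is_sex_chromosome(chroms, dialect: str = "ucsc") -> np.ndarray:
    """Boolean mask for chrX/chrY under the declared naming dialect.

    Matching is case-insensitive and tolerant of a missing/present "chr"
    prefix (``dialect="ucsc"`` accepts both "chrX" and "X").
    """
    ser = pd.Series(chroms, dtype=str).str.lower()
    if dialect in ("ucsc", "mixed"):
        ser = ser.str.removeprefix("chr")
    elif dialect == "ensembl":
        pass
    else:
        raise ValueError(f"unknown chromosome-naming dialect {dialect!r}")
    return ser.isin(_SEX_CHROM_BASES).to_numpy()


def drop_sex_chromosomes(obj, dialect: str = "ucsc"):
    """Remove chrX/chrY rows from an interval table or a peak-indexed matrix.

    Accepts either an interval DataFrame (``chrom`` column) or a count/value
    matrix whose index holds ``chrom:start-end`` peak ids.
    """
    if "chrom" in getattr(obj, "columns", []):
        mask = is_sex_chromosome(obj["chrom"], dialect)
        return obj.loc[~mask].reset_index(drop=True)
    chroms = [str(i).split(":", 1)[0] for i in obj.index]
    mask = is_sex_chromosome(chroms, dialect)
    return obj.loc[~mask]


def _overlap_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """For each query interval: does it intersect >=1 bp of any subject interval?

    Subject intervals need not be disjoint; they are merged internally.
    """
    subject = merge_intervals(subject, bookended=False) if len(subject) else subject
    hits = np.zeros(len(query), dtype=bool)
    if len(subject) == 0 or len(query) == 0:
        return hits
    by_chrom = {c: g for c, g in subject.groupby("chrom")}
    for chrom, grp in query.groupby("chrom"):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        s_starts = sub["start"].to_numpy()
        s_ends = sub["end"].to_numpy()
        q_starts = grp["start"].to_numpy()
        q_ends = grp["end"].to_numpy()
        # merged subject is sorted+disjoint: candidate = last interval starting
        # before the query end; it overlaps iff its end exceeds the query start
        idx = np.searchsorted(s_starts, q_ends, side="left") - 1
        ok = idx >= 0
        overl = np.zeros(len(grp), dtype=bool)
        overl[ok] = s_ends[idx[ok]] > q_starts[ok]
        hits[query.index.get_indexer(grp.index)] = overl
    return hits


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Public vectorized >=1 bp overlap test (query rows vs subject set)."""
    q = validate_intervals(query).reset_index(drop=True)
    s = validate_intervals(subject) if len(subject) else subject
    return _overlap_any(q, s)


def multiset_overlap(sets) -> dict[frozenset, int]:
    """Binary peak-overlap cells for 2-4 named interval sets.

    ``sets`` is a mapping name -> interval table, or a sequence of
    (name, table) pairs.  The inputs are unioned into one merged peak set;
    each union peak is assigned the combination of input sets it intersects
    by >=1 bp.  Returns the count of union peaks per combination
    (Venn-diagram cells).
    """
    pairs = list(sets.items()) if hasattr(sets, "items") else list(sets)
    names = [n for n, _ in pairs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate set names")
    sets = dict(pairs)
    if not 2 <= len(names) <= 4:
        raise ValueError("multiset_overlap takes between 2 and 4 named sets")
    merged = {n: merge_intervals(validate_intervals(s)) for n, s in sets.items()}
    union = merge_peak_sets(list(merged.values()))
    counts: dict[frozenset, int] = {}
    if union.empty:
        return counts
    membership = {n: _overlap_any(union, m) for n, m in merged.items()}
    for i in range(len(union)):
        key = frozenset(n for n in names if membership[n][i])
        counts[key] = counts.get(key, 0) + 1
    return counts
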