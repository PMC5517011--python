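"""Unique Fragment Identifier (UFI) processing.

In a saturated-transposition library, a sequenced fragment's exact start
and end positions on the reference genome act as a natural molecular
barcode: reads sharing the coordinate pair are amplification or sampling
duplicates of one physical fragment, while abutting UFIs
(``end == next start``) can be chained to reconstruct, and count, the
physical DNA copies they came from.

This module filters aligned fragments (mapping quality, size, multi-hit),
consolidates duplicates by UFI, computes the duplication rate
(total reads / total UFIs), and infers a minimum physical-copy count as a
minimum chain cover of the unique fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "READ_COLUMNS",
    "AlignedFragment",
    "UFIKey",
    "DedupReport",
    "validate_fragments",
    "filter_fragments",
    "assign_ufi",
    "consolidate",
    "duplication_rate",
    "dedup",
    "select_region",
    "min_copy_count",
    "link_chains",
]

#: Canonical column order for aligned-fragment tables.
READ_COLUMNS = ["chrom", "start", "end", "mapq", "multi_hit"]
#: Canonical column order for unique-fragment (consolidated) tables.
UNIQUE_COLUMNS = ["chrom", "start", "end", "read_count"]


@dataclass(frozen=True)
class AlignedFragment:
    """One sequenced fragment in reference coordinates (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    mapq: int = 60
    multi_hit: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment end must exceed start: {self}")
        if self.mapq < 0:
            raise ValueError(f"mapping quality must be >= 0: {self}")


class UFIKey(NamedTuple):
    """Exact (chromosome, start, end) identity of a physical fragment."""

    chrom: str
    start: int
    end: int


@dataclass
class DedupReport:
    """Filter tallies and duplication summary for one library."""

    total_reads: int
    reads_failing_mapq: int
    reads_failing_size: int
    reads_multi_hit: int
    reads_retained: int
    total_ufis: int | None = None
    duplication_rate: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _frame(records) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of AlignedFragment records."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = list(records)
    if rows and isinstance(rows[0], AlignedFragment):
        return pd.DataFrame([asdict(r) for r in rows], columns=READ_COLUMNS)
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def validate_fragments(records: pd.DataFrame) -> None:
    """Reject malformed records (end <= start)."""
    if len(records) and not (records["end"].to_numpy() > records["start"].to_numpy()).all():
        bad = int((records["end"].to_numpy() <= records["start"].to_numpy()).sum())
        raise ValueError(f"{bad} malformed record(s) with end <= start")


def filter_fragments(
    records,
    mapq_min: int = 20,
    max_size: int = 500,
) -> tuple[pd.DataFrame, DedupReport]:
    """Remove low-quality, oversized and multi-hit fragments.

    A fragment is retained iff ``mapq >= mapq_min``, its size is at most
    ``max_size`` (strictly over 500 bp is removed; 500 itself passes) and
    it is not a multi-hit.  Removal tallies follow the precedence
    mapq -> size -> multi-hit, so each read is counted once.
    """
    df = _frame(records)
    validate_fragments(df)
    size = df["end"].to_numpy() - df["start"].to_numpy() if len(df) else np.array([], dtype=np.int64)
    mapq = df["mapq"].to_numpy() if len(df) else np.array([], dtype=np.int64)
    multi = df["multi_hit"].to_numpy().astype(bool) if len(df) else np.array([], dtype=bool)
    fail_mapq = mapq < mapq_min
    fail_size = ~fail_mapq & (size > max_size)
    fail_multi = ~fail_mapq & ~fail_size & multi
    keep = ~(fail_mapq | fail_size | fail_multi)
    report = DedupReport(
        total_reads=len(df),
        reads_failing_mapq=int(fail_mapq.sum()),
        reads_failing_size=int(fail_size.sum()),
        reads_multi_hit=int(fail_multi.sum()),
        reads_retained=int(keep.sum()),
    )
    return df.loc[keep].reset_index(drop=True), report


def assign_ufi(record) -> UFIKey:
    """The UFI of a fragment: its exact reference coordinates, verbatim."""
    if isinstance(record, (AlignedFragment, UFIKey)):
        return UFIKey(record.chrom, record.start, record.end)
    if isinstance(record, pd.Series) or isinstance(record, dict):
        return UFIKey(str(record["chrom"]), int(record["start"]), int(record["end"]))
    chrom, start, end = record[0], record[1], record[2]
    return UFIKey(str(chrom), int(start), int(end))


def consolidate(records) -> pd.DataFrame:
    """Collapse reads sharing a UFI into unique fragments with read counts.

    Returns a frame ``chrom, start, end, read_count`` sorted by
    coordinate; the read counts sum to the input size.  Idempotent when a
    consolidated table (``read_count`` column present) is passed back in:
    counts are summed per UFI.
    """
    df = _frame(records)
    if len(df) == 0:
        return pd.DataFrame(columns=UNIQUE_COLUMNS).astype(
            {"start": np.int64, "end": np.int64, "read_count": np.int64}
        )
    if "read_count" not in df.columns:
        df = df.assign(read_count=np.int64(1))
    out = (
        df.groupby(["chrom", "start", "end"], observed=True, as_index=False)["read_count"]
        .sum()
        .sort_values(["chrom", "start", "end"], kind="mergesort")
        .reset_index(drop=True)
    )
    out["chrom"] = out["chrom"].astype(str)
    return out[UNIQUE_COLUMNS]


def duplication_rate(total_reads: int, total_ufis: int) -> float:
    """Total reads divided by total UFIs (>= 1; 1.0 means no duplicates)."""
    if total_ufis <= 0:
        raise ValueError("duplication rate is undefined without UFIs")
    return total_reads / total_ufis


def dedup(records, mapq_min: int = 20, max_size: int = 500) -> tuple[pd.DataFrame, DedupReport]:
    """Filter, consolidate and summarise in one pass."""
    kept, report = filter_fragments(records, mapq_min=mapq_min, max_size=max_size)
    unique = consolidate(kept)
    report.total_ufis = len(unique)
    if len(unique):
        report.duplication_rate = duplication_rate(report.reads_retained, report.total_ufis)
    return unique, report


def select_region(records, chrom: str, start: int, end: int) -> pd.DataFrame:
    """Fragments properly overlapping ``chrom:[start, end)`` (no truncation)."""
    df = _frame(records)
    mask = (df["chrom"].astype(str) == chrom) & (df["start"] < end) & (df["end"] > start)
    return df.loc[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Physical-copy linking
# ---------------------------------------------------------------------------
#
# Strict mode chains u -> v iff end(u) == start(v) on the same chromosome
# (saturated-tiling adjacency).  That adjacency graph decomposes into
# vertex-disjoint complete bipartite blocks keyed by (chrom, boundary
# position) — a fragment appears as predecessor only at its own end and as
# successor only at its own start — so a maximum matching is obtained by
# pairing greedily within each block, and the minimum path cover is
# n_fragments - sum over positions of min(#ending here, #starting here).


def link_chains(fragments) -> list[list[UFIKey]]:
    """One concrete minimum chain cover under strict (abutting) adjacency.

    Every unique fragment appears in exactly one chain; within a chain
    consecutive fragments abut exactly.  When several fragments start at
    a shared boundary, the successor with the smallest end (then
    lexicographic order) is preferred, which fixes the output without
    affecting the number of chains.
    """
    df = consolidate(fragments)
    if len(df) == 0:
        return []
    chains: list[list[UFIKey]] = []
    for chrom, sub in df.groupby("chrom", observed=True, sort=True):
        keys = [UFIKey(str(chrom), int(s), int(e)) for s, e in zip(sub["start"], sub["end"])]
        # successors available at each start position, sorted by (end, start)
        by_start: dict[int, list[int]] = {}
        for i, k in sorted(enumerate(keys), key=lambda ik: (ik[1].end, ik[1].start)):
            by_start.setdefault(k.start, []).append(i)
        nxt: dict[int, int] = {}
        has_prev: set[int] = set()
        for i, k in enumerate(keys):  # predecessors in coordinate order
            cands = by_start.get(k.end)
            if cands:
                j = cands.pop(0)
                nxt[i] = j
                has_prev.add(j)
                if not cands:
                    del by_start[k.end]
        for i in range(len(keys)):
            if i in has_prev:
                continue
            chain = [keys[i]]
            j = i
            while j in nxt:
                j = nxt[j]
                chain.append(keys[j])
            chains.append(chain)
    return chains


def _max_overlap_depth(starts: np.ndarray, ends: np.ndarray) -> int:
    # Half-open intervals: an end event at x closes before a start at x,
    # so touching fragments do not stack.
    events = np.concatenate(
        [np.stack([starts, np.ones_like(starts)], axis=1), np.stack([ends, -np.ones_like(ends)], axis=1)]
    )
    order = np.lexsort((events[:, 1], events[:, 0]))
    depth = np.cumsum(events[order, 1])
    return int(depth.max())


def min_copy_count(fragments, mode: str = "strict") -> int:
    """Minimum number of physical copies consistent with the fragments.

    ``strict`` counts chains under exact abutment (``end(u) == start(v)``):
    the minimum path cover of the adjacency DAG.  ``permissive`` allows a
    gap (``end(u) <= start(v)``); by Dilworth's theorem on interval orders
    this equals the maximum number of fragments properly overlapping any
    single point, computed by a sweep line.  Returns 0 on empty input.
    Chains never cross chromosomes.
    """
    df = consolidate(fragments)
    if len(df) == 0:
        return 0
    if mode == "strict":
        return len(link_chains(df))
    if mode == "permissive":
        total = 0
        for _, sub in df.groupby("chrom", observed=True):
            total += _max_overlap_depth(sub["start"].to_numpy(), sub["end"].to_numpy())
        return total
    raise ValueError(f"unknown mode {mode!r} (expected 'strict' or 'permissive')")
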