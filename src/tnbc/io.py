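"""Readers and writers for aligned-fragment tables.

The canonical interchange format is a 6-column BED-like TSV
(``chrom  start  end  name  mapq  multi_hit``), 0-based half-open.
SAM/BAM input (bowtie2 output or similar) is collapsed pair-wise: a
proper pair becomes one fragment spanning the template, since the UFI is
a property of the sequenced fragment, not of either read.  Alignment
itself is out of scope — this module consumes an aligner's output.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genome import CopySegment, GenomeSpec
from .ufi import READ_COLUMNS, UNIQUE_COLUMNS, validate_fragments

__all__ = [
    "read_alignments",
    "write_fragments",
    "write_unique_fragments",
    "read_unique_fragments",
    "fig1_fixture",
]

logger = logging.getLogger(__name__)

_BED_COLUMNS = ["chrom", "start", "end", "name", "mapq", "multi_hit"]


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".sam", ".bam", ".cram"):
        return "sam"
    if suffix in (".bed", ".tsv", ".txt"):
        return "bed"
    raise ValueError(f"cannot infer alignment format from {path.name!r}; pass format=")


def _read_bed(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=_BED_COLUMNS,
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_BED_COLUMNS)
    df["mapq"] = df.get("mapq", pd.Series(dtype=np.int64)).fillna(60).astype(np.int64)
    df["multi_hit"] = df.get("multi_hit", pd.Series(dtype=np.int64)).fillna(0).astype(np.int64).astype(bool)
    out = df[READ_COLUMNS].copy()
    validate_fragments(out)
    return out


def _read_sam(path: Path, mapq0_is_multi_hit: bool = True) -> pd.DataFrame:
    """Collapse proper pairs to template-span fragments.

    The leftmost mate of each proper pair (positive template length)
    yields the fragment ``[start, start + tlen)`` with that record's
    mapping quality.  A read name seen on a secondary or supplementary
    record is flagged multi-hit, as is (optionally) any fragment with
    mapping quality 0, the common aligner convention for ambiguous
    placement.  Unpaired or improperly paired records are skipped with a
    logged count.
    """
    rows = []
    names = []
    multi_names: set[str] = set()
    skipped = 0
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                multi_names.add(rec.query_name)
                continue
            if rec.is_unmapped:
                skipped += 1
                continue
            if not (rec.is_paired and rec.is_proper_pair) or rec.mate_is_unmapped:
                skipped += 1
                continue
            tlen = rec.template_length
            if tlen <= 0:  # keep only the leftmost mate; one fragment per pair
                continue
            rows.append((rec.reference_name, rec.reference_start, rec.reference_start + tlen, rec.mapping_quality))
            names.append(rec.query_name)
    if skipped:
        logger.warning("skipped %d unpaired/unmapped record(s) in %s", skipped, path)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "mapq"])
    multi = np.array([n in multi_names for n in names], dtype=bool)
    if mapq0_is_multi_hit and len(df):
        multi |= df["mapq"].to_numpy() == 0
    df["multi_hit"] = multi if len(df) else pd.Series(dtype=bool)
    out = df[READ_COLUMNS].copy() if len(df) else pd.DataFrame(columns=READ_COLUMNS)
    validate_fragments(out)
    return out


def read_alignments(path, format: str | None = None, mapq0_is_multi_hit: bool = True) -> pd.DataFrame:
    """Read aligned fragments from SAM/BAM or BED-like TSV.

    Returns the canonical fragment table (``chrom, start, end, mapq,
    multi_hit``), coordinates 0-based half-open.
    """
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt in ("sam", "bam"):
        return _read_sam(path, mapq0_is_multi_hit=mapq0_is_multi_hit)
    if fmt == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_fragments(fragments: pd.DataFrame, path) -> None:
    """Write a fragment table as 6-column BED (name, mapq, multi_hit).

    Rows are sorted by coordinate; ``read_alignments`` inverts this
    exactly.  An empty table produces a header-only file.
    """
    path = Path(path)
    df = fragments.copy()
    if "name" not in df.columns:
        df["name"] = df["copy_id"].astype(str) if "copy_id" in df.columns else [
            f"f{i}" for i in range(len(df))
        ]
    if "mapq" not in df.columns:
        df["mapq"] = 60
    if "multi_hit" not in df.columns:
        df["multi_hit"] = False
    df["multi_hit"] = df["multi_hit"].astype(int)
    df = df[_BED_COLUMNS].sort_values(["chrom", "start", "end"], kind="mergesort")
    with path.open("w") as fh:
        fh.write("#" + "\t".join(_BED_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def write_unique_fragments(unique: pd.DataFrame, path) -> None:
    """Write consolidated unique fragments as BED with score = read count."""
    path = Path(path)
    df = unique[UNIQUE_COLUMNS].sort_values(["chrom", "start", "end"], kind="mergesort").copy()
    df.insert(3, "name", [f"u{i}" for i in range(len(df))])
    with path.open("w") as fh:
        fh.write("#chrom\tstart\tend\tname\tread_count\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_unique_fragments(path) -> pd.DataFrame:
    """Read a unique-fragment BED written by :func:`write_unique_fragments`."""
    try:
        df = pd.read_csv(
            Path(path),
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "name", "read_count"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "read_count": np.int64},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=UNIQUE_COLUMNS)
    return df[UNIQUE_COLUMNS]


def fig1_fixture() -> tuple[GenomeSpec, pd.DataFrame]:
    """The three-copy worked example on a 1,000-base toy chromosome.

    A cell with two haploids and one extra copy over the middle region:
    haploid 1 fragments H1j (24,101), H1k (101,301) and H1l (301,360)
    abut and chain into one physical copy, with H1k sequenced three
    times (amplification duplicates to consolidate).  H2j (95,305) and
    Exi (90,310) — coordinates illustrative — overlap H1k without
    sharing an endpoint, so the three fragments over the overlap region
    are mutually exclusive and witness three physical copies.
    """
    spec = GenomeSpec(
        chromosomes=(("toy", 1000),),
        copy_segments=(
            CopySegment("toy", 0, 90, 2),
            CopySegment("toy", 90, 310, 3),
            CopySegment("toy", 310, 1000, 2),
        ),
    )
    rows = [
        ("toy", 24, 101, "H1j"),
        ("toy", 101, 301, "H1k"),
        ("toy", 101, 301, "H1k"),
        ("toy", 101, 301, "H1k"),
        ("toy", 301, 360, "H1l"),
        ("toy", 95, 305, "H2j"),
        ("toy", 90, 310, "Exi"),
    ]
    reads = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    reads["mapq"] = np.int64(60)
    reads["multi_hit"] = False
    return spec, reads[READ_COLUMNS + ["name"]]
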