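"""Genome specifications for single-cell library simulation.

A :class:`GenomeSpec` describes the reference side of a simulated single
cell: chromosome names and lengths, and a table of disjoint *copy
segments*, each carrying an integer copy count (the number of physical
DNA molecules spanning that interval in the cell).  A normal diploid
autosome is a single segment with ``copy_count=2``; a heterozygous gain
appears as a segment with ``copy_count=3``; a deletion as
``copy_count=0``.

All coordinates are 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

__all__ = [
    "CopySegment",
    "GenomeSpec",
    "chromosome_class",
    "diploid_male",
    "gm01202",
    "gm01202_passage50",
]


def chromosome_class(name: str) -> str:
    """Classify a chromosome name as ``'autosome'``, ``'X'`` or ``'Y'``.

    Recognises ``X``/``Y`` with or without a ``chr`` prefix, case
    insensitively; everything else is an autosome.
    """
    stem = name.lower().removeprefix("chr").upper()
    if stem == "X":
        return "X"
    if stem == "Y":
        return "Y"
    return "autosome"


@dataclass(frozen=True)
class CopySegment:
    """One genomic interval present at an integer number of physical copies."""

    chrom: str
    start: int
    end: int
    copy_count: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end must exceed start: {self}")
        if self.copy_count < 0:
            raise ValueError(f"copy_count must be >= 0: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosomes, copy segments and fragmentation parameters for one cell.

    Parameters
    ----------
    chromosomes
        ``(name, length)`` pairs; names must be unique.
    copy_segments
        Disjoint intervals per chromosome with non-negative copy counts.
        Overlapping segments on one chromosome are rejected: a region
        whose copy number differs from its surroundings must be split
        into disjoint pieces.
    mean_insert
        Mean fragment length (bases) produced by saturated transposition.
    min_fragment
        Hard lower bound on fragment length (bases); 50 for Mu
        transposase (Tn5 would be 35).
    """

    chromosomes: tuple[tuple[str, int], ...]
    copy_segments: tuple[CopySegment, ...]
    mean_insert: int = 150
    min_fragment: int = 50

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        object.__setattr__(self, "copy_segments", tuple(self.copy_segments))
        names = [n for n, _ in self.chromosomes]
        if not names:
            raise ValueError("at least one chromosome is required")
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.min_fragment < 1:
            raise ValueError("min_fragment must be >= 1")
        if self.mean_insert <= self.min_fragment:
            raise ValueError("mean_insert must exceed min_fragment")
        lengths = dict(self.chromosomes)
        by_chrom: dict[str, list[CopySegment]] = {}
        for seg in self.copy_segments:
            if seg.chrom not in lengths:
                raise ValueError(f"segment on unknown chromosome: {seg}")
            if seg.start < 0 or seg.end > lengths[seg.chrom]:
                raise ValueError(f"segment outside chromosome bounds: {seg}")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs.sort(key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping copy segments on {chrom}: "
                        f"[{a.start},{a.end}) and [{b.start},{b.end}); "
                        "split overlapping regions into disjoint segments"
                    )

    # -- derived quantities -------------------------------------------------

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def genome_bases(self) -> int:
        """Total reference bases across chromosomes (one haploid pass)."""
        return sum(l for _, l in self.chromosomes)

    @property
    def total_copy_bases(self) -> int:
        """Total bases over all physical copies (sum of length x copy_count)."""
        return sum(s.length * s.copy_count for s in self.copy_segments)

    def segments_for(self, chrom: str) -> list[CopySegment]:
        return sorted((s for s in self.copy_segments if s.chrom == chrom), key=lambda s: s.start)

    # -- serialisation ------------------------------------------------------

    def to_table(self, path: str | Path) -> None:
        """Write the spec as a plain-text table.

        Lines beginning with ``@`` declare chromosomes and scalar
        parameters; remaining lines are tab-separated segment rows
        ``chrom  start  end  copy_count``.
        """
        path = Path(path)
        lines = ["# TnBC genome specification"]
        for name, length in self.chromosomes:
            lines.append(f"@chromosome\t{name}\t{length}")
        lines.append(f"@mean_insert\t{self.mean_insert}")
        lines.append(f"@min_fragment\t{self.min_fragment}")
        for s in sorted(self.copy_segments, key=lambda s: (s.chrom, s.start)):
            lines.append(f"{s.chrom}\t{s.start}\t{s.end}\t{s.copy_count}")
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "GenomeSpec":
        """Read a spec written by :meth:`to_table`."""
        chromosomes: list[tuple[str, int]] = []
        segments: list[CopySegment] = []
        params: dict[str, int] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if line.startswith("@"):
                key = fields[0][1:]
                if key == "chromosome":
                    chromosomes.append((fields[1], int(fields[2])))
                elif key in ("mean_insert", "min_fragment"):
                    params[key] = int(fields[1])
                else:
                    raise ValueError(f"{path}:{lineno}: unknown directive {fields[0]!r}")
            else:
                if len(fields) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
                segments.append(CopySegment(fields[0], int(fields[1]), int(fields[2]), int(fields[3])))
        return cls(tuple(chromosomes), tuple(segments), **params)


# ---------------------------------------------------------------------------
# Desk-scale presets
# ---------------------------------------------------------------------------
#
# These use scaled-down chromosomes (a few Mb each) so that a whole
# fragmentation/amplification/sampling run completes in seconds; the
# copy-number structure, not the absolute genome size, is what downstream
# bin statistics depend on once reads-per-bin is fixed.


def _autosomes(n: int, length: int) -> list[tuple[str, int]]:
    return [(f"chr{i}", length) for i in range(1, n + 1)]


def diploid_male(
    n_autosomes: int = 8,
    autosome_length: int = 12_000_000,
    x_length: int = 12_000_000,
    y_length: int = 6_000_000,
    mean_insert: int = 150,
    min_fragment: int = 50,
) -> GenomeSpec:
    """Normal diploid male karyotype: autosomes CN 2, single X and Y."""
    chroms = _autosomes(n_autosomes, autosome_length) + [("chrX", x_length), ("chrY", y_length)]
    segs = [CopySegment(f"chr{i}", 0, autosome_length, 2) for i in range(1, n_autosomes + 1)]
    segs += [CopySegment("chrX", 0, x_length, 1), CopySegment("chrY", 0, y_length, 1)]
    return GenomeSpec(tuple(chroms), tuple(segs), mean_insert, min_fragment)


def gm01202(
    n_autosomes: int = 12,
    autosome_length: int = 8_000_000,
    x_length: int = 8_000_000,
    y_length: int = 4_000_000,
    mean_insert: int = 150,
    min_fragment: int = 50,
) -> GenomeSpec:
    """GM01202-like karyotype: four copies of X, two of each autosome, one Y."""
    chroms = _autosomes(n_autosomes, autosome_length) + [("chrX", x_length), ("chrY", y_length)]
    segs = [CopySegment(f"chr{i}", 0, autosome_length, 2) for i in range(1, n_autosomes + 1)]
    segs += [CopySegment("chrX", 0, x_length, 4), CopySegment("chrY", 0, y_length, 1)]
    return GenomeSpec(tuple(chroms), tuple(segs), mean_insert, min_fragment)


def gm01202_passage50(**kwargs) -> GenomeSpec:
    """Late-passage GM01202 derivative: whole-chromosome-12 trisomy plus a
    trisomic segment on chromosome 3 (segment coordinates are illustrative)."""
    base = gm01202(**kwargs)
    length = base.chrom_lengths["chr3"]
    gain_start, gain_end = length // 4, 3 * length // 4
    segs = []
    for s in base.copy_segments:
        if s.chrom == "chr12":
            segs.append(replace(s, copy_count=3))
        elif s.chrom == "chr3":
            segs += [
                CopySegment("chr3", 0, gain_start, 2),
                CopySegment("chr3", gain_start, gain_end, 3),
                CopySegment("chr3", gain_end, length, 2),
            ]
        else:
            segs.append(s)
    return GenomeSpec(base.chromosomes, tuple(segs), base.mean_insert, base.min_fragment)
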