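"""Generative model of a transposon-barcoded (TnBC) single-cell library.

The model follows the library's life cycle:

1. **Physical copies.**  Each copy segment of a :class:`~tnbc.genome.GenomeSpec`
   yields one contiguous DNA molecule per copy (``build_physical_copies``).
2. **Saturated transposition.**  Each molecule is cut into short abutting
   fragments that tile it exactly.  Fragment lengths are
   ``min_fragment + Geometric`` with mean ``mean_insert`` — a memoryless
   excess over the transposase's hard footprint floor (50 bases for Mu).
   The last fragment of a molecule is the leftover remainder and may be
   shorter than the floor, since molecule ends are not transposon-bounded.
3. **Single-primer PCR.**  Each fragment's molecule count evolves as a
   branching process: per cycle every existing molecule duplicates with
   probability ``p = cycle_efficiency(length, config)``.  Efficiency falls
   for short inserts and for long terminal repeats (hairpin formation in
   single-primer PCR), which is why the engineered 18-base stem (Mu18)
   amplifies ahead of the 50-base wildtype stem.
4. **Sequencing.**  Reads are a multinomial sample over molecules; with
   noise off each read reports the fragment's exact reference
   coordinates (mapping quality 60, unique hit).

Coordinates are 0-based half-open throughout; abutting fragments share a
boundary position (``end_i == start_{i+1}``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .genome import GenomeSpec
from .ufi import READ_COLUMNS

__all__ = [
    "PhysicalCopy",
    "AmplificationConfig",
    "AmplifiedLibrary",
    "NoiseConfig",
    "SimulationResult",
    "build_physical_copies",
    "saturated_fragmentation",
    "fragment_genome",
    "cycle_efficiency",
    "amplify",
    "sample_reads",
    "expected_library_size",
    "ideal_library",
    "cycles_to_fold",
    "simulate_cell",
]

FRAGMENT_COLUMNS = ["copy_id", "chrom", "start", "end", "terminal"]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PhysicalCopy:
    """One contiguous DNA molecule spanning a reference interval."""

    copy_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"physical copy must have end > start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


def build_physical_copies(spec: GenomeSpec, seed: int | None = 0) -> list[PhysicalCopy]:
    """Expand copy segments into physical molecules, one per copy.

    Deterministic given the spec; ``seed`` is reserved for future
    end-position jitter.  A segment with ``copy_count=0`` (deletion)
    yields nothing.
    """
    copies: list[PhysicalCopy] = []
    for seg in sorted(spec.copy_segments, key=lambda s: (s.chrom, s.start)):
        for i in range(seg.copy_count):
            copies.append(
                PhysicalCopy(f"{seg.chrom}:{seg.start}-{seg.end}#{i}", seg.chrom, seg.start, seg.end)
            )
    return copies


def _draw_fragment_lengths(rng: np.random.Generator, n: int, min_fragment: int, mean_insert: int) -> np.ndarray:
    # Geometric on {1,2,...} with mean m+1, shifted: excess on {0,1,...} with
    # mean m = mean_insert - min_fragment.
    p = 1.0 / (mean_insert - min_fragment + 1.0)
    return min_fragment + rng.geometric(p, size=n) - 1


def saturated_fragmentation(
    copy: PhysicalCopy,
    min_fragment: int = 50,
    mean_insert: int = 150,
    seed=0,
) -> pd.DataFrame:
    """Cut one physical copy into abutting fragments that tile it exactly.

    Returns a frame with columns ``copy_id, chrom, start, end, terminal``;
    ``terminal`` marks the remainder fragment at the molecule's right end,
    the only one allowed to be shorter than ``min_fragment``.  A copy
    shorter than ``min_fragment`` becomes a single whole-copy fragment.
    """
    rng = _as_rng(seed)
    L = copy.length
    if L <= min_fragment:
        boundaries = np.array([0, L], dtype=np.int64)
    else:
        pieces = []
        covered = 0
        while covered < L:
            need = max(int((L - covered) / mean_insert * 1.2) + 16, 16)
            lengths = _draw_fragment_lengths(rng, need, min_fragment, mean_insert)
            pieces.append(lengths)
            covered += int(lengths.sum())
        lengths = np.concatenate(pieces)
        cum = np.cumsum(lengths)
        k = int(np.searchsorted(cum, L, side="left"))  # first index with cum >= L
        boundaries = np.concatenate([[0], cum[: k + 1]])
        boundaries[-1] = L
    starts = copy.start + boundaries[:-1]
    ends = copy.start + boundaries[1:]
    n = len(starts)
    terminal = np.zeros(n, dtype=bool)
    terminal[-1] = True
    return pd.DataFrame(
        {
            "copy_id": pd.Categorical([copy.copy_id] * n),
            "chrom": pd.Categorical([copy.chromosome] * n),
            "start": starts.astype(np.int64),
            "end": ends.astype(np.int64),
            "terminal": terminal,
        }
    )


def fragment_genome(spec: GenomeSpec, seed=0) -> pd.DataFrame:
    """Saturated transposition of every physical copy of a genome spec.

    One independent counter-based random stream per copy (spawned from the
    master seed), so the result is reproducible and order-independent.
    """
    copies = build_physical_copies(spec)
    if not copies:
        return pd.DataFrame(columns=FRAGMENT_COLUMNS)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(len(copies))
    parts = [
        saturated_fragmentation(c, spec.min_fragment, spec.mean_insert, np.random.default_rng(s))
        for c, s in zip(copies, streams)
    ]
    out = pd.concat(parts, ignore_index=True)
    out["copy_id"] = out["copy_id"].astype("category")
    out["chrom"] = out["chrom"].astype("category")
    return out


# ---------------------------------------------------------------------------
# Amplification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AmplificationConfig:
    """Per-cycle replication efficiency model for single-primer PCR.

    ``cycle_efficiency`` is a product of two logistic factors: one rising
    with insert length (short inserts fold into hairpins more readily),
    one falling with stem (terminal-repeat) length.  ``stem_length`` is 18
    for the engineered Mu18 transposon and 50 for wildtype Mu.

    The logistic midpoints/scales are a numerical calibration chosen so
    that, over the saturated-transposition length distribution, a
    stem-18 library reaches a 10^6-fold amplification threshold about
    three cycles before a stem-50 library (see ``cycles_to_fold``).
    """

    cycles: int = 7
    stem_length: int = 18
    efficiency_max: float = 0.95
    length_halfpoint: float = 40.0
    length_scale: float = 15.0
    stem_halfpoint: float = 66.0
    stem_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency_max <= 1.0:
            raise ValueError("efficiency_max must be in [0, 1]")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")


def cycle_efficiency(insert_length, config: AmplificationConfig):
    """Per-cycle duplication probability for a fragment of given length.

    Monotone non-decreasing in insert length, non-increasing in stem
    length; saturates at ``efficiency_max``.  Vectorised over
    ``insert_length``.
    """
    length = np.asarray(insert_length, dtype=float)
    if np.any(length < 1):
        raise ValueError("insert_length must be >= 1")
    length_factor = expit((length - config.length_halfpoint) / config.length_scale)
    stem_factor = expit((config.stem_halfpoint - config.stem_length) / config.stem_scale)
    p = config.efficiency_max * length_factor * stem_factor
    if np.isscalar(insert_length):
        return float(p)
    return p


@dataclass
class AmplifiedLibrary:
    """Fragments plus their post-PCR molecule counts (each >= 1: the
    original molecule persists through amplification)."""

    fragments: pd.DataFrame
    molecule_counts: np.ndarray

    def __post_init__(self) -> None:
        if len(self.fragments) != len(self.molecule_counts):
            raise ValueError("fragments and molecule_counts must align")
        if len(self.molecule_counts) and self.molecule_counts.min() < 1:
            raise ValueError("molecule counts must be >= 1")

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def total_molecules(self) -> int:
        return int(self.molecule_counts.sum())

    @property
    def entries(self):
        """Iterate ``(chrom, start, end, molecule_count)`` tuples."""
        for (chrom, start, end), n in zip(
            zip(self.fragments["chrom"], self.fragments["start"], self.fragments["end"]),
            self.molecule_counts,
        ):
            yield chrom, int(start), int(end), int(n)


def amplify(fragments: pd.DataFrame, config: AmplificationConfig) -> AmplifiedLibrary:
    """Branching-process PCR: per cycle each molecule duplicates with
    probability ``cycle_efficiency(length)``; expected final count is
    ``(1 + p) ** cycles``.  The set of distinct fragment coordinates (the
    UFIs) is unchanged by amplification."""
    rng = np.random.default_rng(config.seed)
    lengths = (fragments["end"] - fragments["start"]).to_numpy()
    counts = np.ones(len(fragments), dtype=np.int64)
    if len(fragments) == 0:
        return AmplifiedLibrary(fragments.copy(), counts)
    p = np.asarray(cycle_efficiency(lengths, config), dtype=float)
    for _ in range(config.cycles):
        counts = counts + rng.binomial(counts, p)
    return AmplifiedLibrary(fragments.reset_index(drop=True), counts)


def cycles_to_fold(insert_lengths: Sequence[int], config: AmplificationConfig, fold: float = 1e6) -> float:
    """Fractional number of cycles for the expected library yield to reach
    ``fold`` times its input, i.e. solve ``mean((1+p_i)^c) = fold``.

    This is the in-silico analogue of an amplification-to-threshold (Ct)
    readout; the difference between stem-18 and stem-50 configurations is
    the "cycle gap" between the engineered and wildtype transposons.
    """
    lengths = np.asarray(insert_lengths, dtype=float)
    p = np.asarray(cycle_efficiency(lengths, config), dtype=float)
    if np.all(p == 0):
        raise ValueError("no fragment amplifies; threshold unreachable")

    def log_yield(c: float) -> float:
        # log of mean((1+p)^c), stable via logsumexp-style scaling
        g = c * np.log1p(p)
        m = g.max()
        return m + np.log(np.exp(g - m).mean()) - np.log(fold)

    hi = 2.0
    while log_yield(hi) < 0:
        hi *= 2.0
    return float(brentq(log_yield, 0.0, hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseConfig:
    """Optional imperfections injected into sampled reads (all off by
    default): a fraction of reads with degraded mapping quality, a
    fraction flagged as multi-hit, and integer jitter on coordinates."""

    low_mapq_rate: float = 0.0
    multi_hit_rate: float = 0.0
    jitter_sd: float = 0.0


def sample_reads(
    library: AmplifiedLibrary,
    n_reads: int,
    seed=0,
    noise: NoiseConfig | None = None,
) -> pd.DataFrame:
    """Multinomial read sampling proportional to molecule counts.

    Returns an aligned-fragment table (``chrom, start, end, mapq,
    multi_hit``); with noise off every read carries its fragment's exact
    coordinates, mapping quality 60 and ``multi_hit=False``.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if len(library) == 0:
        raise ValueError("cannot sample from an empty library")
    rng = _as_rng(seed)
    cum = np.cumsum(library.molecule_counts)
    draws = rng.integers(0, cum[-1], size=n_reads)
    idx = np.searchsorted(cum, draws, side="right")
    reads = library.fragments.iloc[idx][["chrom", "start", "end"]].reset_index(drop=True)
    reads["chrom"] = reads["chrom"].astype("category")
    reads["mapq"] = np.int16(60)
    reads["multi_hit"] = False
    if noise is not None and n_reads > 0:
        if noise.jitter_sd > 0:
            jit = np.rint(rng.normal(0.0, noise.jitter_sd, size=(n_reads, 2))).astype(np.int64)
            reads["start"] = np.maximum(reads["start"].to_numpy() + jit[:, 0], 0)
            reads["end"] = np.maximum(reads["end"].to_numpy() + jit[:, 1], reads["start"].to_numpy() + 1)
        if noise.low_mapq_rate > 0:
            hit = rng.random(n_reads) < noise.low_mapq_rate
            reads.loc[hit, "mapq"] = rng.integers(0, 20, size=int(hit.sum())).astype(np.int16)
        if noise.multi_hit_rate > 0:
            reads["multi_hit"] = rng.random(n_reads) < noise.multi_hit_rate
    return reads[READ_COLUMNS]


def expected_library_size(genome_bases: int, mean_insert: int) -> int:
    """Expected number of molecules in a 1X saturated-transposition
    library: genome bases divided by mean insert size (rounded)."""
    if genome_bases <= 0 or mean_insert <= 0:
        raise ValueError("genome_bases and mean_insert must be positive")
    return int(round(genome_bases / mean_insert))


def ideal_library(
    n_molecules: int,
    insert_length: int = 150,
    chromosome: str = "chr1",
    spacing: int = 1,
) -> AmplifiedLibrary:
    """A perfectly uniform library: ``n_molecules`` distinct fragments at
    one molecule each, starts ``spacing`` bases apart.  Used for
    closed-form duplication-rate and sampling-noise-floor checks."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    starts = np.arange(n_molecules, dtype=np.int64) * spacing
    frags = pd.DataFrame(
        {
            "chrom": pd.Categorical([chromosome] * n_molecules),
            "start": starts,
            "end": starts + insert_length,
        }
    )
    return AmplifiedLibrary(frags, np.ones(n_molecules, dtype=np.int64))


# ---------------------------------------------------------------------------
# Whole-cell convenience pipeline
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Everything one simulated sequencing run produced."""

    spec: GenomeSpec
    fragments: pd.DataFrame
    library: AmplifiedLibrary
    reads: pd.DataFrame
    n_reads: int


def simulate_cell(
    spec: GenomeSpec,
    n_reads: int | None = None,
    reads_per_bin: float | None = None,
    bin_kb: int = 1000,
    config: AmplificationConfig | None = None,
    seed: int = 0,
    noise: NoiseConfig | None = None,
    base_ploidy: int = 2,
) -> SimulationResult:
    """Fragment, amplify and sample one cell end to end.

    Either give ``n_reads`` directly or ``reads_per_bin``, in which case
    the read total is chosen so a bin of ``bin_kb`` at the base ploidy
    receives that many reads on average.
    """
    if (n_reads is None) == (reads_per_bin is None):
        raise ValueError("give exactly one of n_reads or reads_per_bin")
    if n_reads is None:
        n_reads = int(round(reads_per_bin * spec.total_copy_bases / (base_ploidy * bin_kb * 1000)))
    ss = np.random.SeedSequence(seed).spawn(3)
    fragments = fragment_genome(spec, ss[0])
    cfg = config or AmplificationConfig()
    cfg = AmplificationConfig(**{**cfg.__dict__, "seed": int(np.random.default_rng(ss[1]).integers(2**31))})
    library = amplify(fragments, cfg)
    reads = sample_reads(library, n_reads, np.random.default_rng(ss[2]), noise=noise)
    return SimulationResult(spec, fragments, library, reads, n_reads)
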