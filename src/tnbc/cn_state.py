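"""Bin-based copy-number-state inference and call-confidence scoring.

Per-bin read counts are normalised to continuous copy values by
``value = base_ploidy * count / center``, with the center taken as the
median autosomal bin count (robust to focal gains and losses), and
rounded half-up to integer states.  No segmentation is performed: the
evidence of interest is the *distribution* of continuous values — tight,
well-separated peaks at the integer states mean confident calls, merged
peaks mean the library was too noisy for the chosen resolution.

The ``separation_score`` quantifies the valley between two adjacent
state peaks in that distribution (1 = clean separation, 0 = no valley),
and ``required_reads`` gives the read total needed to keep a fixed
reads-per-bin confidence level at a finer bin resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import chromosome_class
from .uniformity import BinCounts

__all__ = [
    "CNStateProfile",
    "CNDistribution",
    "infer_cn",
    "cn_distribution",
    "separation_score",
    "required_reads",
]


@dataclass
class CNStateProfile:
    """Per-bin continuous copy values and rounded integer states."""

    bins: pd.DataFrame  # chrom, start, end
    counts: np.ndarray
    values: np.ndarray  # continuous copy value per bin (>= 0)
    states: np.ndarray  # integer state = round-half-up(value)
    base_ploidy: int
    center: float  # normalisation center (median autosomal count)

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["count"] = self.counts
        out["copy_value"] = self.values
        out["state"] = self.states
        return out

    def chrom_classes(self) -> np.ndarray:
        return np.array([chromosome_class(c) for c in self.bins["chrom"]])

    def modal_state(self, chrom_class: str | None = None) -> int:
        """Most common integer state, optionally within one chromosome
        class ('autosome', 'X' or 'Y')."""
        states = self.states
        if chrom_class is not None:
            states = states[self.chrom_classes() == chrom_class]
        if len(states) == 0:
            raise ValueError(f"no bins in class {chrom_class!r}")
        values, freq = np.unique(states, return_counts=True)
        return int(values[np.argmax(freq)])


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.int64)


def infer_cn(bin_counts: BinCounts, base_ploidy: int = 2) -> CNStateProfile:
    """Normalise bin counts to copy values and round to integer states.

    The center is the median count over autosomal bins (all bins if the
    scheme has no autosomes); sex chromosomes are not special-cased, so a
    male cell's X and Y land at state 1 purely through their counts.
    Scale-invariant: multiplying every count by a constant changes
    nothing.
    """
    counts = np.asarray(bin_counts.counts, dtype=float)
    if len(counts) < 10:
        raise ValueError("need at least 10 bins for copy-number inference")
    if counts.sum() <= 0:
        raise ValueError("all-zero bin counts")
    bins = bin_counts.scheme.bins
    classes = np.array([chromosome_class(c) for c in bins["chrom"]])
    autosomal = counts[classes == "autosome"]
    center = float(np.median(autosomal if len(autosomal) else counts))
    if center <= 0:
        raise ValueError("normalisation center is zero; coverage too sparse")
    values = base_ploidy * counts / center
    return CNStateProfile(
        bins=bins.copy(),
        counts=np.asarray(bin_counts.counts),
        values=values,
        states=_round_half_up(values),
        base_ploidy=base_ploidy,
        center=center,
    )


@dataclass
class CNDistribution:
    """Histogram of continuous copy values plus per-class modal states."""

    edges: np.ndarray  # histogram cell edges (uniform width)
    frequencies: np.ndarray  # bins per cell; sums to number of genome bins
    width: float
    modal_states: dict[str, int]
    values: np.ndarray  # the underlying continuous values
    states: np.ndarray

    def density_at(self, x: float, halfwidth: float | None = None) -> float:
        """Mean histogram frequency over cells whose center lies within
        ``x +/- halfwidth`` (default: one cell width)."""
        if halfwidth is None:
            halfwidth = self.width
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        mask = np.abs(centers - x) <= halfwidth + 1e-12
        if not mask.any():
            return 0.0
        return float(self.frequencies[mask].mean())

    def peak_density(self, state: float, halfwidth: float = 0.25) -> float:
        """Max histogram frequency among cells within ``state +/- halfwidth``."""
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        mask = np.abs(centers - state) <= halfwidth + 1e-12
        if not mask.any():
            return 0.0
        return float(self.frequencies[mask].max())


def cn_distribution(profile: CNStateProfile, histogram_width: float = 0.05) -> CNDistribution:
    """Histogram the continuous copy values (cell width in copies)."""
    values = profile.values
    top = float(values.max()) + 2 * histogram_width
    edges = np.arange(0.0, top + histogram_width, histogram_width)
    freq, edges = np.histogram(values, bins=edges)
    classes = profile.chrom_classes()
    modal = {
        cls: profile.modal_state(cls)
        for cls in ("autosome", "X", "Y")
        if (classes == cls).any()
    }
    return CNDistribution(edges, freq, histogram_width, modal, values, profile.states)


def separation_score(distribution: CNDistribution, state_a: int, state_b: int) -> float:
    """How cleanly two integer-state peaks separate, in [0, 1].

    ``1 - valley / min(peaks)``, clamped to [0, 1], where the valley is
    the mean histogram density within one cell of the midpoint
    ``(a+b)/2`` and each peak is the maximum density within a quarter
    copy of its state.  1 means delta-like disjoint peaks; 0 means the
    histogram is flat (or rising) between them.  Both states must be
    supported by at least 5 genome bins.
    """
    if state_a == state_b:
        raise ValueError("states must differ")
    a, b = sorted((state_a, state_b))
    for s in (a, b):
        if int((distribution.states == s).sum()) < 5:
            raise ValueError(f"state {s} supported by fewer than 5 bins")
    peak_a = distribution.peak_density(a)
    peak_b = distribution.peak_density(b)
    if min(peak_a, peak_b) <= 0:
        raise ValueError("no histogram mass near one of the states")
    valley = distribution.density_at((a + b) / 2.0)
    return float(np.clip(1.0 - valley / min(peak_a, peak_b), 0.0, 1.0))


def required_reads(resolution_kb: float, reads_per_bin: float, mappable_genome_bases: float) -> int:
    """Total reads needed for ``reads_per_bin`` coverage at a given bin
    resolution: (mappable genome / bin size) * reads per bin.

    At 1,000 kb bins and 400 reads/bin on a 2.5 Gb mappable genome this
    is the familiar 1 M-read shallow run; tightening resolution to 50 kb
    at the same confidence costs 20 M reads (about 1X coverage).
    """
    if resolution_kb <= 0 or mappable_genome_bases <= 0:
        raise ValueError("resolution and genome size must be positive")
    if reads_per_bin < 0:
        raise ValueError("reads_per_bin must be >= 0")
    return int(round(mappable_genome_bases / (resolution_kb * 1000.0) * reads_per_bin))
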