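"""Coverage-uniformity evaluation: binning, Lorenz curves, Gini index.

A library's evenness is scored by downsampling to a fixed read total
(1,000,000 by default), counting reads in genome bins of equal mappable
content, and summarising the count distribution as a Lorenz curve — the
cumulative share of reads carried by the poorest fraction of bins — and
its Gini index.  A perfectly uniform library sits on the diagonal
(Gini 0); amplification bias bows the curve downward.  Because counting
noise shrinks as bins grow, the Gini falls with bin size even for an
unbiased library; comparisons are made at a fixed bin size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ufi import consolidate, _frame

__all__ = [
    "DEFAULT_BIN_SIZES_KB",
    "BinScheme",
    "BinCounts",
    "LorenzResult",
    "downsample",
    "make_bins",
    "count_per_bin",
    "lorenz",
    "gini_vs_binsize",
    "plot_lorenz",
]

#: Bin sizes (kb) used for the Gini-versus-resolution sweep.
DEFAULT_BIN_SIZES_KB = [50, 100, 250, 500, 1000, 2500, 5000, 10000]


@dataclass
class BinScheme:
    """Ordered, disjoint genome bins of equal mappable content."""

    bins: pd.DataFrame  # columns chrom, start, end (sorted, disjoint)
    nominal_size_kb: float

    def __len__(self) -> int:
        return len(self.bins)


@dataclass
class BinCounts:
    """Per-bin read (or unique-fragment) counts for one scheme."""

    scheme: BinScheme
    counts: np.ndarray
    outside: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        out = self.scheme.bins.copy()
        out["count"] = self.counts
        return out


@dataclass
class LorenzResult:
    """Piecewise-linear Lorenz curve and its Gini index.

    ``points`` is an ``(n_bins+1, 2)`` array of (cumulative fraction of
    bins, cumulative fraction of reads) from (0,0) to (1,1), bins sorted
    by ascending count so the curve lies on or below the diagonal.
    """

    points: np.ndarray
    gini: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["cum_fraction_bins", "cum_fraction_reads"])


def downsample(records, n: int = 1_000_000, seed=0) -> pd.DataFrame:
    """Uniform sample of exactly ``n`` records without replacement."""
    df = _frame(records)
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > len(df):
        raise ValueError(
            f"cannot downsample {len(df)} records to {n}; use all reads instead"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(df), size=n, replace=False))
    return df.iloc[idx].reset_index(drop=True)


def _uniform_bins_for(length: int, width: int) -> np.ndarray:
    edges = np.arange(0, length, width, dtype=np.int64)
    return np.append(edges, length)


def make_bins(genome, nominal_size_kb: float, mappability: pd.DataFrame | None = None) -> BinScheme:
    """Partition a genome into bins of equal mappable content.

    ``genome`` is a list of ``(name, length)`` pairs or anything with a
    ``chromosomes`` attribute.  With no mappability mask every position
    counts, so bins have fixed physical length (the last bin of each
    chromosome may be short; a chromosome shorter than one bin is a
    single whole-chromosome bin).  A mask — a frame of mappable intervals
    ``chrom, start, end`` — stretches bins so each holds
    ``nominal_size_kb * 1000`` mappable positions.
    """
    if nominal_size_kb <= 0:
        raise ValueError("nominal_size_kb must be positive")
    chromosomes = getattr(genome, "chromosomes", genome)
    width = int(round(nominal_size_kb * 1000))
    rows = []
    for name, length in chromosomes:
        if mappability is None:
            edges = _uniform_bins_for(int(length), width)
        else:
            sub = mappability[mappability["chrom"] == name].sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            sizes = ends - starts
            cum = np.concatenate([[0], np.cumsum(sizes)])
            total_mappable = int(cum[-1])
            if total_mappable == 0:
                continue
            targets = np.arange(width, total_mappable, width)
            # genomic position where cumulative mappable content crosses t
            seg = np.searchsorted(cum, targets, side="left") - 1
            pos = starts[seg] + (targets - cum[seg])
            edges = np.concatenate([[0], pos, [int(length)]]).astype(np.int64)
        for s, e in zip(edges[:-1], edges[1:]):
            rows.append((name, int(s), int(e)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return BinScheme(bins, nominal_size_kb)


def count_per_bin(records, scheme: BinScheme, unit: str = "reads") -> BinCounts:
    """Assign each record to the bin containing its fragment midpoint.

    ``unit='unique_fragments'`` consolidates by UFI first, so every
    distinct fragment counts once.  Records on chromosomes absent from
    the scheme (or beyond its span) are tallied as ``outside``.
    """
    if unit == "unique_fragments":
        df = consolidate(records)
    elif unit == "reads":
        df = _frame(records)
    else:
        raise ValueError(f"unknown unit {unit!r}")
    df = df.reset_index(drop=True)
    counts = np.zeros(len(scheme), dtype=np.int64)
    outside = 0
    bins = scheme.bins
    offsets = {}
    for chrom, sub in bins.groupby("chrom", sort=False):
        offsets[chrom] = (sub.index[0], sub["start"].to_numpy(), sub["end"].to_numpy())
    mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2 if len(df) else np.array([], dtype=np.int64)
    for chrom, sub in df.groupby("chrom", observed=True):
        m = mid[sub.index.to_numpy()]
        if str(chrom) not in offsets:
            outside += len(sub)
            continue
        first, bstarts, bends = offsets[str(chrom)]
        idx = np.searchsorted(bends, m, side="right")
        ok = (idx < len(bends)) & (m >= bstarts[np.minimum(idx, len(bends) - 1)])
        outside += int((~ok).sum())
        np.add.at(counts, first + idx[ok], 1)
    return BinCounts(scheme, counts, outside)


def lorenz(bin_counts: BinCounts | np.ndarray) -> LorenzResult:
    """Lorenz curve and Gini index of a set of bin counts.

    Bins are sorted by ascending count; the Gini is one minus twice the
    trapezoidal area under the piecewise-linear curve, so it is exact for
    the discrete curve and 0 iff all counts are equal.
    """
    counts = bin_counts.counts if isinstance(bin_counts, BinCounts) else np.asarray(bin_counts)
    if counts.sum() <= 0:
        raise ValueError("Lorenz curve undefined for zero total reads")
    c = np.sort(counts.astype(float))
    n = len(c)
    x = np.arange(n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(c)]) / c.sum()
    gini = 1.0 - 2.0 * float(np.trapezoid(y, x))
    return LorenzResult(np.column_stack([x, y]), gini)


def gini_vs_binsize(
    records,
    genome,
    sizes_kb: Sequence[float] = DEFAULT_BIN_SIZES_KB,
    mappability: pd.DataFrame | None = None,
    unit: str = "reads",
) -> pd.DataFrame:
    """Gini index at each bin size, on the same record set throughout."""
    df = _frame(records)
    if len(df) == 0:
        raise ValueError("no records")
    rows = []
    for size in sizes_kb:
        scheme = make_bins(genome, size, mappability=mappability)
        bc = count_per_bin(df, scheme, unit=unit)
        rows.append((size, lorenz(bc).gini))
    return pd.DataFrame(rows, columns=["size_kb", "gini"])


def plot_lorenz(results: dict[str, LorenzResult], path: str | Path) -> None:
    """Write a Lorenz-curve comparison plot (one labelled curve per entry)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect uniformity")
    for label, res in results.items():
        ax.plot(res.points[:, 0], res.points[:, 1], label=f"{label} (Gini {res.gini:.3f})")
    ax.set_xlabel("cumulative fraction of bins")
    ax.set_ylabel("cumulative fraction of reads")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
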