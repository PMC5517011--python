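import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_reads(rows):
    """Build a canonical aligned-fragment table from (chrom, start, end[, mapq[, multi]]) tuples."""
    full = []
    for r in rows:
        chrom, start, end = r[0], r[1], r[2]
        mapq = r[3] if len(r) > 3 else 60
        multi = bool(r[4]) if len(r) > 4 else False
        full.append((chrom, start, end, mapq, multi))
    return pd.DataFrame(full, columns=["chrom", "start", "end", "mapq", "multi_hit"])


def chain_cover_oracle(fragments, permissive=False):
    """Exhaustive minimum chain cover over all chain partitions.

    ``fragments`` is a list of (chrom, start, end) tuples (duplicates are
    collapsed, matching consolidation).  Strict chaining requires exact
    abutment; permissive allows a gap.  Feasible for n <= 12.
    """
    frags = sorted(set(fragments))
    n = len(frags)
    if n == 0:
        return 0

    def can_follow(pred, succ):
        if pred[0] != succ[0]:
            return False
        return pred[2] <= succ[1] if permissive else pred[2] == succ[1]

    best = [n]

    def rec(i, tails):
        if len(tails) >= best[0]:
            return
        if i == n:
            best[0] = len(tails)
            return
        f = frags[i]
        tried = set()
        for k, t in enumerate(tails):
            if t not in tried and can_follow(t, f):
                tried.add(t)
                tails[k] = f
                rec(i + 1, tails)
                tails[k] = t
        tails.append(f)
        rec(i + 1, tails)
        tails.pop()

    rec(0, [])
    return best[0]


def random_fragment_set(rng, n_max=12, coord_max=12):
    """Small random half-open intervals with frequent shared endpoints."""
    n = int(rng.integers(0, n_max + 1))
    frags = []
    for _ in range(n):
        chrom = "chr1" if rng.random() < 0.8 else "chr2"
        start = int(rng.integers(0, coord_max))
        end = int(rng.integers(start + 1, coord_max + 3))
        frags.append((chrom, start, end))
    return frags


@pytest.fixture
def fig1():
    from tnbc.io import fig1_fixture

    return fig1_fixture()


@pytest.fixture
def tiny_spec():
    from tnbc.genome import CopySegment, GenomeSpec

    return GenomeSpec(
        chromosomes=(("chr1", 5000),),
        copy_segments=(CopySegment("chr1", 0, 5000, 1),),
    )
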