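"""Generative model: physical copies, saturated fragmentation, PCR
branching amplification, read sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tnbc.genome import CopySegment, GenomeSpec
from tnbc.simulate import (
    AmplificationConfig,
    PhysicalCopy,
    amplify,
    build_physical_copies,
    cycle_efficiency,
    cycles_to_fold,
    expected_library_size,
    fragment_genome,
    ideal_library,
    sample_reads,
    saturated_fragmentation,
)
from tnbc.ufi import consolidate


def saturated_config(**kw):
    """Config whose logistic factors are exactly saturated, so the
    per-cycle probability equals efficiency_max."""
    return AmplificationConfig(
        length_halfpoint=1.0, length_scale=1e-3, stem_halfpoint=1e6, stem_scale=1e-3, **kw
    )


class TestPhysicalCopies:
    def test_diploid_segment_yields_two_copies(self):
        spec = GenomeSpec((("chr1", 1000),), (CopySegment("chr1", 100, 900, 2),))
        copies = build_physical_copies(spec)
        assert len(copies) == 2
        assert all((c.chromosome, c.start, c.end) == ("chr1", 100, 900) for c in copies)
        assert len({c.copy_id for c in copies}) == 2

    def test_extra_copy_region_counts(self):
        # diploid background with an extra copy over the middle, expressed
        # as disjoint segments with counts (2, 2, 3, 2)
        spec = GenomeSpec(
            (("chr1", 4000),),
            (
                CopySegment("chr1", 0, 1000, 2),
                CopySegment("chr1", 1000, 2000, 2),
                CopySegment("chr1", 2000, 3000, 3),
                CopySegment("chr1", 3000, 4000, 2),
            ),
        )
        copies = build_physical_copies(spec)
        per_region = pd.Series([c.start for c in copies]).value_counts().sort_index()
        assert per_region.tolist() == [2, 2, 3, 2]

    def test_zero_copy_segment_is_a_deletion(self):
        spec = GenomeSpec((("chr1", 1000),), (CopySegment("chr1", 0, 1000, 0),))
        assert build_physical_copies(spec) == []

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            GenomeSpec(
                (("chr1", 1000),),
                (CopySegment("chr1", 0, 600, 2), CopySegment("chr1", 400, 1000, 3)),
            )

    def test_deterministic(self):
        spec = GenomeSpec((("chr1", 1000),), (CopySegment("chr1", 0, 1000, 3),))
        assert build_physical_copies(spec) == build_physical_copies(spec)


class TestSaturatedFragmentation:
    @given(st.integers(60, 5000), st.integers(0, 2**31 - 1))
    def test_fragments_tile_copy_exactly(self, length, seed):
        copy = PhysicalCopy("c", "chr1", 10, 10 + length)
        frags = saturated_fragmentation(copy, seed=seed)
        assert frags["start"].iloc[0] == copy.start
        assert frags["end"].iloc[-1] == copy.end
        # abutting: each end equals the next start; lengths sum to copy length
        assert (frags["end"].to_numpy()[:-1] == frags["start"].to_numpy()[1:]).all()
        assert int((frags["end"] - frags["start"]).sum()) == length

    def test_minimum_length_floor(self):
        frags = saturated_fragmentation(PhysicalCopy("c", "chr1", 0, 2_000_000), seed=3)
        lengths = (frags["end"] - frags["start"]).to_numpy()
        assert len(lengths) >= 10_000
        assert lengths[:-1].min() == 50  # hard transposase footprint floor

    def test_length_distribution(self):
        frags = saturated_fragmentation(PhysicalCopy("c", "chr1", 0, 2_000_000), seed=4)
        lengths = (frags["end"] - frags["start"]).to_numpy()[:-1]
        assert abs(lengths.mean() - 150) < 5
        # geometric excess: P(length > 500) = P(excess > 450) ~ exp(-4.5) ~ 0.011
        assert (lengths > 500).mean() < 0.05

    def test_short_copy_becomes_single_fragment(self):
        frags = saturated_fragmentation(PhysicalCopy("c", "chr1", 100, 130), seed=0)
        assert len(frags) == 1
        assert (frags["start"].iloc[0], frags["end"].iloc[0]) == (100, 130)

    def test_only_terminal_fragment_may_break_floor(self):
        frags = saturated_fragmentation(PhysicalCopy("c", "chr1", 0, 100_000), seed=5)
        lengths = (frags["end"] - frags["start"]).to_numpy()
        assert (lengths[:-1] >= 50).all()
        assert frags["terminal"].to_numpy()[-1]
        assert not frags["terminal"].to_numpy()[:-1].any()

    def test_same_seed_reproduces(self):
        copy = PhysicalCopy("c", "chr1", 0, 50_000)
        a = saturated_fragmentation(copy, seed=11)
        b = saturated_fragmentation(copy, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestCycleEfficiency:
    def test_saturation_limit(self):
        cfg = saturated_config(efficiency_max=0.95)
        assert cycle_efficiency(300, cfg) == pytest.approx(0.95)

    def test_stem_and_length_ordering(self):
        for stem in (18, 50):
            cfg = AmplificationConfig(stem_length=stem)
            assert cycle_efficiency(300, cfg) >= cycle_efficiency(50, cfg)
        for L in (50, 150, 300, 1000):
            p18 = cycle_efficiency(L, AmplificationConfig(stem_length=18))
            p50 = cycle_efficiency(L, AmplificationConfig(stem_length=50))
            assert p18 >= p50

    @given(st.integers(1, 2000), st.integers(1, 1999))
    def test_monotone_in_insert_length(self, length, delta):
        cfg = AmplificationConfig()
        assert cycle_efficiency(length + delta, cfg) >= cycle_efficiency(length, cfg)

    def test_three_cycle_gap_between_stems(self):
        # amplification-to-threshold readout: the engineered 18-base stem
        # reaches a 1e6-fold yield about three cycles before wildtype
        frags = saturated_fragmentation(PhysicalCopy("c", "chr1", 0, 1_500_000), seed=2)
        lengths = (frags["end"] - frags["start"]).to_numpy()[:-1]
        c18 = cycles_to_fold(lengths, AmplificationConfig(stem_length=18))
        c50 = cycles_to_fold(lengths, AmplificationConfig(stem_length=50))
        assert 2.5 <= c50 - c18 <= 3.5


class TestAmplify:
    def _frags(self, n, length=150):
        starts = np.arange(n, dtype=np.int64) * length
        return pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + length})

    def test_certain_duplication_doubles_exactly(self):
        lib = amplify(self._frags(20), saturated_config(efficiency_max=1.0, cycles=6))
        assert (lib.molecule_counts == 2**6).all()

    def test_zero_efficiency_keeps_originals(self):
        lib = amplify(self._frags(20), saturated_config(efficiency_max=0.0, cycles=30))
        assert (lib.molecule_counts == 1).all()

    def test_branching_process_mean(self):
        # E[count] = (1 + p)^cycles; check at three standard errors
        lib = amplify(self._frags(1000), saturated_config(efficiency_max=0.9, cycles=10, seed=8))
        counts = lib.molecule_counts.astype(float)
        expected = 1.9**10
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se

    def test_amplification_preserves_ufi_set(self):
        frags = saturated_fragmentation(PhysicalCopy("c", "chr1", 0, 20_000), seed=1)
        lib = amplify(frags, AmplificationConfig(cycles=8, seed=1))
        before = set(zip(frags["chrom"].astype(str), frags["start"], frags["end"]))
        after = set(zip(lib.fragments["chrom"].astype(str), lib.fragments["start"], lib.fragments["end"]))
        assert before == after
        assert lib.molecule_counts.min() >= 1


class TestSampleReads:
    def test_zero_reads(self):
        lib = ideal_library(10)
        assert len(sample_reads(lib, 0, seed=0)) == 0

    def test_negative_reads_rejected(self):
        with pytest.raises(ValueError):
            sample_reads(ideal_library(10), -1, seed=0)

    def test_single_fragment_library(self):
        lib = ideal_library(1)
        reads = sample_reads(lib, 100, seed=0)
        assert len(reads) == 100
        assert reads[["chrom", "start", "end"]].astype({"chrom": str}).nunique().tolist() == [1, 1, 1]
        assert (reads["mapq"] == 60).all() and (~reads["multi_hit"]).all()

    def test_same_seed_is_bit_identical(self):
        lib = ideal_library(1000)
        a = sample_reads(lib, 500, seed=42)
        b = sample_reads(lib, 500, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_occupancy_matches_closed_form(self):
        # duplication rate n / (U (1 - (1 - 1/U)^n)) for uniform sampling
        U, n = 20_000, 5_000
        reads = sample_reads(ideal_library(U), n, seed=9)
        ufis = len(consolidate(reads))
        expected_distinct = U * (1 - (1 - 1 / U) ** n)
        assert abs(ufis - expected_distinct) < 4 * np.sqrt(expected_distinct)


class TestExpectedLibrarySize:
    @pytest.mark.parametrize(
        "genome,insert,expected",
        [(6_000_000_000, 300, 20_000_000), (6_000_000_000, 150, 40_000_000), (300, 300, 1)],
    )
    def test_division(self, genome, insert, expected):
        assert expected_library_size(genome, insert) == expected

    def test_zero_insert_rejected(self):
        with pytest.raises(ValueError):
            expected_library_size(1000, 0)


class TestGenomePipeline:
    def test_sampled_ufis_subset_of_primary_fragments(self, tiny_spec):
        frags = fragment_genome(tiny_spec, seed=0)
        lib = amplify(frags, AmplificationConfig(cycles=5, seed=0))
        reads = sample_reads(lib, 200, seed=0)
        frag_set = set(zip(frags["chrom"].astype(str), frags["start"], frags["end"]))
        read_set = set(zip(reads["chrom"].astype(str), reads["start"], reads["end"]))
        assert read_set <= frag_set

    def test_deep_sampling_saturates_coverage(self, tiny_spec):
        frags = fragment_genome(tiny_spec, seed=1)
        lib = amplify(frags, AmplificationConfig(cycles=3, seed=1))
        reads = sample_reads(lib, 20_000, seed=1)
        frag_set = set(zip(frags["chrom"].astype(str), frags["start"], frags["end"]))
        read_set = set(zip(reads["chrom"].astype(str), reads["start"], reads["end"]))
        assert read_set == frag_set

    def test_fragment_genome_reproducible(self, tiny_spec):
        pd.testing.assert_frame_equal(fragment_genome(tiny_spec, 7), fragment_genome(tiny_spec, 7))
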