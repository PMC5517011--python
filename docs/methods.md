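# Methods

## The generative model

A simulated cell is described by a `GenomeSpec`: chromosomes with
lengths, and disjoint *copy segments*, each an interval present at an
integer number of physical copies (0-based, half-open coordinates
throughout).  The simulator follows the physical life of a TnBC
library:

**1. Physical copies.**  Each copy segment with count *k* yields *k*
contiguous molecules over that interval.  A diploid chromosome is two
molecules; a trisomic region appears as disjoint segments with counts
(2, 3, 2); a deletion has count 0.

**2. Saturated transposition.**  Each molecule is cut into abutting
fragments that tile it exactly (each fragment's end is the next one's
start; lengths sum to the molecule length).  Fragment length is

```
length = min_fragment + Geometric(mean = mean_insert − min_fragment)
```

on integers ≥ 0.  The hard floor models the transposase footprint —
two loaded transposases binding side by side cannot cut closer than 50
bases for Mu (35 for Tn5) — and the memoryless excess is the simplest
law consistent with cut sites packing at random beyond that exclusion
distance.  With the Mu defaults (floor 50, mean 150) the bulk of
fragments falls in the 50–300 base range and
P(length > 500) = exp(−450/100) ≈ 0.011, i.e. the library is
essentially free of poorly-sequenced long inserts.  The **terminal
remainder** of each molecule is whatever is left at its right end and
may be shorter than the floor: molecule ends are not transposon-bounded,
and exact tiling is required for UFI chain linking.  No quantitative
fragment-length law is established experimentally; the geometric-excess
choice is this package's own.

**3. Single-primer PCR.**  Amplicons whose two ends are identical
terminal repeats fold into hairpins, so per-cycle replication
efficiency falls for short inserts and for long stems.  We model the
per-cycle duplication probability as

```
p(L) = efficiency_max · σ((L − length_halfpoint)/length_scale)
                      · σ((stem_halfpoint − stem_length)/stem_scale)
```

with σ the logistic function; each fragment's molecule count then
evolves as a Galton–Watson branching process (`count += Binomial(count,
p)` per cycle), so the expected count after *c* cycles is `(1+p)^c` and
the original molecule always persists.  Amplification never changes the
set of distinct fragment coordinates — the UFIs are invariant.

*Calibration.*  Defaults are `efficiency_max = 0.95`,
`length_halfpoint = 40`, `length_scale = 15`, `stem_halfpoint = 66`,
`stem_scale = 10`.  The stem parameters were calibrated numerically so
that, over the saturated-transposition length distribution, the
expected yield of a stem-18 library (engineered Mu18 transposon)
reaches a 10⁶-fold threshold ≈3 cycles before a stem-50 (wildtype)
library — the in-silico analogue of the observed Ct advantage
(`cycles_to_fold` computes this threshold; the test band is 2.5–3.5
cycles).  At these defaults p(150, 18) ≈ 0.94 and p(150, 50) ≈ 0.79.

**4. Sequencing.**  Reads are a multinomial sample over molecules
(probability ∝ molecule count).  With noise off, each read reports its
fragment's exact coordinates with mapping quality 60 and no multi-hit
flag — a perfect-alignment contract that makes ground truth available
downstream.  Optional noise knobs (off by default) degrade mapping
quality, flag multi-hits, or jitter coordinates, so the filters can be
exercised against imperfect input.

Randomness uses one master seed; per-molecule streams are spawned
deterministically (`numpy` `SeedSequence`), so results are bit-identical
across runs and independent of evaluation order.

## UFI processing

Filtering retains an aligned fragment iff mapping quality ≥ 20, size
≤ 500 bp ("over 500" is read strictly, so 500 is retained; 19 is
removed, 20 retained), and it is not a multi-hit; removal tallies use
the precedence mapq → size → multi-hit so each read is counted once.
The UFI is the exact (chromosome, start, end) triple — no alignment
wobble is tolerated; tolerant (±1 base) matching would be a possible
extension but is deliberately not implemented.  Consolidation groups
reads by UFI (read counts are conserved) and the duplication rate is
total reads / total UFIs.

**Copy linking.**  Strict-mode chaining joins unique fragments u → v
iff `end(u) == start(v)` on one chromosome.  The minimum number of
chains covering all fragments is a minimum path cover of this DAG
(V − maximum matching).  Because a fragment can act as predecessor only
at its own end position and successor only at its own start, the
bipartite adjacency graph splits into vertex-disjoint complete blocks
keyed by (chromosome, boundary position); the maximum matching is
therefore Σ min(#fragments ending, #fragments starting) per position
and is found greedily — no general matching solver is needed.  Ties
(several fragments sharing a start) are broken toward the successor
with the smallest end, then lexicographically, for deterministic
output.  Permissive mode chains across gaps (`end ≤ start`); by
Dilworth's theorem on interval orders the minimum chain count equals
the maximum number of fragments properly overlapping one point,
computed by a sweep line (end events before start events at equal
coordinates, matching half-open semantics).  Both modes are tested
against an exhaustive partition-search oracle on all inputs of ≤ 12
fragments.

## Uniformity

Reads are downsampled without replacement to a fixed total, assigned to
bins by fragment midpoint (symmetric, no boundary double counting), and
summarised by the Lorenz curve of bin counts sorted ascending; the Gini
index is 1 − 2 × (trapezoidal area under the curve), exact for the
discrete piecewise-linear curve, 0 iff all bins are equal, bounded by
1 − 1/B for B bins.  Bins hold equal *mappable* content: under the
default uniform mappability they are fixed-length (the last bin of a
chromosome may be short); with a mask, bin boundaries are placed where
cumulative mappable positions cross multiples of the nominal size.
Both raw reads and UFI-consolidated unique fragments are supported as
the counting unit.

For an unbiased library at mean *m* reads/bin the Gini sits at the
Poisson(m) sampling floor and falls as bins grow — so Gini is
monotonically non-increasing in bin size, and method comparisons must
fix the bin size.  Amplification dispersion (low per-cycle efficiency
over many cycles, the regime of MALBAC- or MDA-like protocols) raises
the Gini above that floor.  One subtlety the simulation exposes: under
the optimized stem-18 defaults, the slight length dependence of
efficiency *anti-correlates* with the local fragment count (bins that
happen to hold more fragments hold shorter ones), so mild uniform
amplification can sit marginally below the unamplified curve; the
biased-regime ordering is what is asserted in tests.

## Copy-number states

Per-bin continuous copy value = `base_ploidy · count / center`, with
the center the **median autosomal bin count** — robust to focal CNVs,
and deliberately not special-casing sex chromosomes, whose states fall
wherever their counts put them (X and Y report 1 in a normal male).
Integer state = value rounded half-up (2.5 → 3).  No segmentation is
performed: per-bin states and their distribution are the object of
interest, and smoothing would mask exactly the dispersion being
measured.

Call confidence is the separation of adjacent peaks in the histogram of
continuous values (cell width 0.05 copies):
`score = 1 − valley / min(peaks)` clamped to [0, 1], with the valley
the mean density within one cell of the state midpoint and each peak
the maximum density within a quarter copy of its state; both states
must be supported by ≥ 5 bins.  The score is 1 for delta-like disjoint
peaks, 0 for a flat (or rising) profile between them, and decreases
monotonically with per-bin noise.

`required_reads(resolution_kb, reads_per_bin, mappable_bases)` gives
the read budget for a target resolution at fixed per-bin statistical
power: 400 reads/bin at 1,000 kb on a 2.5 Gb mappable genome is a 1 M
read shallow run; the same confidence at 50 kb costs 20 M reads.

## Problem sizes and the synthetic presets

The genome presets are desk-scale: `diploid_male()` is 8 autosomes of
12 Mb plus 12 Mb X and 6 Mb Y; `gm01202()` (4 copies of X, 2 of each
autosome, 1 Y) uses 12 autosomes of 8 Mb so that the passage-50
derivative can carry its whole-chromosome-12 trisomy and a trisomic
chromosome-3 segment (segment coordinates are illustrative; the
published karyotypes do not pin them down).  At 400 reads per 1,000 kb
bin these genomes give ~100 bins and ~45,000 reads per cell, which
preserves the per-bin statistics that matter (reads/bin, fragment
density per bin) while keeping a full
fragmentation–amplification–sampling–analysis cycle under two seconds.
The ideal-library duplication check runs at full scale (20,000,000
molecules, 1,000,000 reads) since it is a pure sampling computation.

## What the simulator does and does not capture

Captured: exact tiling of physical copies (hence UFI chaining and its
copy-count bounds), the fragment-size floor and its effect on mapping,
length- and stem-dependent PCR efficiency with stochastic
branching-process dispersion, multinomial sampling duplicates, and the
reads-per-bin arithmetic connecting resolution to read budget.

Not captured: base-level sequence chemistry and transposase sequence
preference, GC-dependent amplification bias, chimera formation,
alignment errors beyond the optional noise knobs, mappability
estimation from a real reference, and segmentation-based CNV calling.
Passing tests therefore demonstrate the internal consistency of the
model and the correctness of the analysis operations on data with this
structure — not performance on any particular real sequencing run.
Real aligned data can be brought in through the SAM/BAM/BED readers,
which collapse proper pairs to template-span fragments (the UFI belongs
to the fragment, not the read; orientation is not part of the key) and
normalise multi-hit status (secondary/supplementary flags, with
mapping-quality-0 as a dialect-level fallback).

## Numerical and degenerate-input conventions

* One printed inconsistency in the source arithmetic is resolved in
  favour of plain division: `expected_library_size` returns
  genome_bases / mean_insert rounded, so a 6 Gb cell at mean insert 150
  gives 40,000,000 molecules (and 20,000,000 at mean insert 300).
* A molecule shorter than the fragment floor becomes a single
  whole-molecule fragment; a chromosome shorter than one bin becomes a
  single bin.
* Lorenz/Gini reject an all-zero count vector; copy-number inference
  requires ≥ 10 bins, a nonzero autosomal median, and rejects all-zero
  counts; `duplication_rate` rejects zero UFIs; `downsample` rejects
  requests beyond the available reads rather than silently truncating.
* Filtering order-independence, consolidation idempotence and read
  conservation, seed reproducibility, and the Gini bounds are enforced
  as property tests.
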