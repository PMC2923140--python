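# Methods

This note documents the models and procedures implemented in
`peaktools`, the parameters that matter, the numerical conventions, and
what the synthetic data does and does not emulate.

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)`.  GTF
(1-based inclusive) is converted at the parser boundary by
`(start−1, end)`; WIG fixedStep/variableStep positions (1-based) by
`position−1`; BED and bedGraph are taken verbatim.  A single convention
everywhere removes the most common class of interval-arithmetic bugs;
the converters are exercised per record by round-trip tests.

When a WIG file covers a base twice, the later value wins and a warning
is logged; overlapping blocks have no standard semantics and
last-writer-wins is at least deterministic.  Depth is a float, so
tiling-array fluorescence tracks work the same as integral read counts.
BED scores are parsed as floats and not range-checked, because peak
callers routinely emit scores outside the nominal 0–1000 range.

## Subpeak division

Within each peak the dense depth vector is scanned for local maxima: a
position qualifies when its depth exceeds the nearest *differing* depth
on each side (boundaries compare only inward), plateaus are represented
at their leftmost base, and zero-depth positions never qualify.  For
each adjacent pair of maxima with heights *h₁, h₂*, a division threshold
*t = valley_factor · min(h₁, h₂)* is computed; if the minimum depth on
the open interval between them is below *t*, the peak is cut at that
minimum (leftmost base on ties), with the valley base assigned to the
right-hand subpeak.  Before any height filtering the subpeaks tile the
parent exactly — no gaps, no overlaps — which is asserted as an
invariant.

Parameters:

* `valley_factor` (unitless, in (0, 1], default **0.6**) — the single
  knob of the division rule.  Higher values split more readily; 0.6
  separates clearly distinct summits without fragmenting plateaus, and
  the subpeak count is provably non-decreasing in this parameter.
* `min_height` (depth units, default **0** = keep everything) —
  subpeaks whose summit depth falls below it are dropped after
  splitting, as one does to suppress spurious low-coverage subpeaks;
  retained counts are non-increasing in this parameter.
* `summit_flank` (bases, default **100**) — half-width of the sequence
  window emitted around each summit for motif discovery; always set it
  consciously for the motif scanner at hand.

Two conventions are under-determined by the division rule and fixed
here for determinism: cuts land on the *valley minimum* (an alternative
would be midway between maxima), and the valley base joins the right
subpeak.  Peaks with no positive signal coverage produce no subpeaks and
a warning rather than an error, since peak and signal files may come
from different caller runs.

## Nested containment list

Annotations in higher eukaryotes contain genes nested inside other
genes, so a start-sorted transcript list does not have sorted ends and
plain binary search breaks.  The index therefore partitions intervals
into a *primary* list — those contained in no other — and, recursively,
per-interval sublists of directly contained intervals.  At every level
starts and ends are both strictly sorted, which the structural tests
assert on random builds.

Construction sorts by (start ascending, end descending, input order) and
assigns containment in one stack pass: O(n log n).  Identical spans keep
the first-encountered interval primary and nest later duplicates under
it, preserving the exactly-one-home property without arbitrary
tie-breaking.  Strand is payload, not an index key: the
downstream-gene query needs interleaved access to both strands, so one
index per chromosome holds everything and strand filtering happens in
the query.

## Nearest downstream gene (NDG)

A forward-strand gene is *downstream* of a peak when its start lies at
or beyond the peak end; a reverse-strand gene when its end lies at or
before the peak start.  Distances are gaps between the peak boundary and
the TSS-side gene boundary (0 = adjacency); transcripts intersecting the
peak by ≥ 1 base are excluded from the nearest slots and reported
separately with a component classification.

The query walks the primary list outward from a binary-search insertion
point.  Because the best candidate can be nested inside another gene —
e.g. a forward gene inside a long reverse gene that spans the peak — the
walk descends into containment sublists, pruned by the fact that an
entry's span bounds everything nested inside it.  The walk is therefore
exact: tests compare it against a quadratic linear scan on hundreds of
randomized nested annotations and require zero mismatches.  Ties are
broken deterministically (smallest start / largest end, then transcript
id), identically in implementation and oracle.

`bidirectional_promoter` is flagged when both downstream genes exist
within `bidir_window` bases (default **1000**, configurable) — a peak
between two divergently transcribed genes.

## Nearest TSS

The peak center is `floor((start + end − 1) / 2)` (even-length peaks
take the left-of-center base).  The TSS of a transcript is `tx_start` on
the forward strand and `tx_end − 1` on the reverse strand.  The query is
a branch-and-bound walk over the NCList: a subtree rooted at an entry
only contains TSS positions inside the entry's span, giving a lower
bound on the attainable distance, and the walk stops when the bound
exceeds the current best.  The reported transcript minimizes
|TSS − center| over *all* transcripts on the chromosome (verified
against the exhaustive scan); ties go to the lexicographically smallest
transcript id and all tied ids are reported.

The signed distance is positive when the peak center lies downstream of
the TSS in the gene's transcription direction, negative when upstream.

## Component classification

Classification is by the peak's *central position*, mapped into the
transcript structure: 5′/3′ UTR (requires an annotated CDS; polarity
follows the strand), CDS-containing exon, or intron with a 1-based rank
counted in transcription order (rank 1 abuts the first exon).  Without a
CDS, exonic hits are reported as exon.  Centers outside the transcript
classify as upstream/downstream relative to the strand.  The function is
total: every center position receives exactly one class per transcript.
An any-overlap variant is available through the NDG result, which lists
every transcript the peak touches.

Profiling summaries group distances into within-gene / ≤1 kb / 1–10 kb /
>10 kb bins per side (edges configurable) and intron ranks into first /
last / higher rank-order introns; single-intron transcripts count as
first intron.

## Dataset overlap and the randomization test

Two loci overlap when they share ≥ 1 base; strand is ignored.  The
second set is indexed once and each query locus is answered through the
NCList (including containment sublists, so a huge interval spanning the
query is found even when only its nested children are near the insertion
point).  The union operation merges intervals across datasets wherever
they intersect — touching intervals stay separate — and records per
merged region which datasets contributed.

The enrichment null preserves each query interval's chromosome and
length and draws its start uniformly on `[0, chrom_length − length]`;
placements may overlap each other (no self-avoidance, which would bias
long-interval placement).  The statistic is the number of query
intervals with at least one partner.  With *N* iterations (default
**1000**) the add-one estimator `p = (1 + #{nᵢ ≥ observed}) / (N + 1)`
is never exactly zero and has floor 1/(N+1) ≈ 0.001 at the default —
reported as "p < 0.001".  Which set is randomized matters; this
implementation randomizes the first-named (query) set and holds the
second fixed.  Calibration is tested empirically: with the query set
itself drawn from the null, the fraction of p ≤ 0.05 over 200 seeded
repetitions must stay near the nominal rate (the binomial 2σ band
[0.02, 0.08] at 200 repetitions).

## Synthetic data

The generator emulates the *inputs* of a peak-calling run — BED peaks,
a WIG depth track, an Ensembl-style GTF, a genome FASTA — at a small
mammalian-like scale.  Defaults: two chromosomes (500 kb + 300 kb), 120
transcripts with 1–8 exons and an 80% CDS rate, 15% of transcripts
nested inside others (to exercise the containment machinery), 80 peaks
carrying 1–4 signal bumps each with summit depths 10–50× over a unit
background, and inter-summit valleys at 30% of the lower flanking
summit.

Signal bumps are *triangular* (linear rise and fall, half-width 100 bp)
rather than Gaussian, deliberately: every planted summit height and
valley depth is then an exact number, so whether any valley divides at a
given valley factor is analytically known and the ground-truth table
fully predicts the splitter's output without re-running any splitting
logic.  The generator shares no algorithmic code with the library.

What the synthetic data does **not** emulate: read-level noise and
mapping artifacts, irregular peak shapes and shoulders, assembly gaps
and unmappable regions, GC and chromatin-accessibility biases in random
placement, and realistic genome/annotation scale.  Passing tests
therefore demonstrate algorithmic correctness on well-formed inputs, not
robustness to every pathology of real tracks; the parsers' validation
and the zero-coverage / missing-chromosome degraded-input paths cover
the common real-data failure modes explicitly.

## Problem sizes in the test suite

The oracle-equivalence suites run 200 randomized annotation sets of up
to 500 transcripts with 5 peaks each (nearest-gene and TSS), 200 random
set pairs for overlap, 1000 random index builds of up to 2000 intervals,
and a calibration experiment of 200 repetitions × 500 iterations with a
100-interval query set against a 150-interval reference on a 2 Mb
genome.  These sizes give the quadratic oracles full coverage of the
nesting edge cases while keeping the default test run to well under a
minute per suite.  `scripts/acceptance.py` uses 200 peaks and 300
transcripts on a 1.7 Mb genome with 1000 randomization iterations.

## Known limitations

* GFF3, BAM and bigWig/bigBed inputs are not parsed; convert to
  GTF/SAM-derived WIG/bedGraph first.
* The randomization null is uniform per chromosome; no masking of
  assembly gaps or blacklisted regions.
* The index is in-memory and rebuilt per run; there is no serialized
  index format.
* Peak strand, when present in BED column 6, is parsed but ignored by
  all annotation queries (overlap is defined on either strand).
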