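"""Synthetic genomes, gene annotations, signal tracks and peak sets with
known ground truth.

The generator emulates the inputs a peak caller hands to this toolkit: a
BED peak file, a WIG track giving per-base read depth inside each peak,
an Ensembl-style GTF and (optionally) a genome FASTA.  Signal bumps are
triangular (linear rise and fall), so every planted summit height and
valley depth is an exact number and the split decision for any
valley_factor is analytically known — the ground-truth table is
sufficient to predict the splitter's output without re-running any
splitting logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import GenomicInterval, SignalProfile, Transcript, ValidationError

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic data.

    Defaults model a small mammalian-style ChIP-seq experiment: peaks a
    few hundred bases long (one to four binding events each), summit read
    depths in the tens, and a transcriptome in which a modest fraction of
    transcripts is nested inside others (overlapping genes are what the
    containment index exists for).
    """

    seed: int = 0
    chromosomes: Tuple[Tuple[str, int], ...] = (("chr1", 500_000), ("chr2", 300_000))
    n_transcripts: int = 120
    nesting_prob: float = 0.15
    exon_count_range: Tuple[int, int] = (1, 8)
    cds_prob: float = 0.8
    n_peaks: int = 80
    summits_per_peak_range: Tuple[int, int] = (1, 4)
    summit_height_range: Tuple[float, float] = (10.0, 50.0)
    valley_depth_fraction: float = 0.3
    background_depth: float = 1.0
    bump_halfwidth: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.nesting_prob <= 1.0):
            raise ValidationError("nesting_prob must be in [0, 1]")
        if not (0.0 < self.valley_depth_fraction < 1.0):
            raise ValidationError("valley_depth_fraction must be in (0, 1)")
        if self.bump_halfwidth < 2:
            raise ValidationError("bump_halfwidth must be >= 2")
        if self.background_depth <= 0:
            raise ValidationError("background_depth must be positive")
        if self.summit_height_range[0] <= self.background_depth:
            raise ValidationError("summit heights must exceed the background depth")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PlantedPeak:
    """Ground truth for one synthetic peak: where the summits were planted
    and how deep each inter-summit valley is."""

    name: str
    chrom: str
    start: int
    end: int
    summits: Tuple[Tuple[int, float], ...]   # (position, height)
    valleys: Tuple[Tuple[int, float], ...]   # (position, depth), len = len(summits)-1

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.name)

    def separable_pairs(self, valley_factor: float) -> List[bool]:
        """Whether each adjacent summit pair is divided at this valley_factor."""
        out = []
        for ((_, h1), (_, h2)), (_, depth) in zip(
            zip(self.summits, self.summits[1:]), self.valleys
        ):
            out.append(depth < valley_factor * min(h1, h2))
        return out

    def expected_subpeaks(self, valley_factor: float) -> int:
        return 1 + sum(self.separable_pairs(valley_factor))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _transcript_structure(
    rng: np.random.Generator, spec: SyntheticSpec
) -> List[Tuple[int, int]]:
    """Exon offsets (relative to 0) for a new top-level transcript."""
    lo, hi = spec.exon_count_range
    n_exons = int(rng.integers(lo, hi + 1))
    exon_lens = rng.integers(100, 501, size=n_exons)
    intron_lens = rng.integers(200, 2001, size=max(n_exons - 1, 0))
    exons = []
    cursor = 0
    for i in range(n_exons):
        exons.append((cursor, cursor + int(exon_lens[i])))
        cursor = exons[-1][1]
        if i < n_exons - 1:
            cursor += int(intron_lens[i])
    return exons


_MIN_HOST_SPAN = 20  # a host must fit a nested transcript strictly inside


def _nested_structure(
    rng: np.random.Generator, max_length: int
) -> List[Tuple[int, int]]:
    """Exon offsets for a transcript nested inside a host.

    Spans scale with the available room (about 70% of it), so chains of
    nested transcripts stay big enough to host further levels.
    """
    span = max(int(max_length * 0.7), 10)
    n_exons = int(rng.integers(1, 4))
    units = 2 * n_exons - 1
    if span < 2 * units:
        n_exons, units = 1, 1
    base = span // units
    exons = []
    for i in range(n_exons):
        start = 2 * i * base
        end = start + base if i < n_exons - 1 else span
        exons.append((start, end))
    return exons


def _pick_cds(
    rng: np.random.Generator, exons: List[Tuple[int, int]]
) -> Tuple[Optional[int], Optional[int]]:
    first_start, first_end = exons[0]
    last_start, last_end = exons[-1]
    cds_start = first_start + int(rng.integers(0, max(first_end - first_start - 1, 1)))
    cds_end = last_end - int(rng.integers(0, max(last_end - last_start - 1, 1)))
    if cds_end <= cds_start:  # degenerate single short exon
        cds_start, cds_end = first_start, last_end
    return cds_start, cds_end


def make_annotation(
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    gtf_path=None,
) -> List[Transcript]:
    """Generate a synthetic transcriptome, optionally writing it as GTF.

    A ``nesting_prob`` fraction of transcripts is placed entirely inside
    the most recently generated transcript (when it is large enough), so
    high nesting probabilities produce containment chains.
    """
    if rng is None:
        rng = spec.rng()
    transcripts: List[Transcript] = []
    for i in range(spec.n_transcripts):
        tid = f"T{i + 1:04d}"
        gid = f"G{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        host = None
        if transcripts and rng.random() < spec.nesting_prob:
            # prefer the latest transcript so chains build up under p = 1
            for candidate in reversed(transcripts):
                if candidate.tx_end - candidate.tx_start >= _MIN_HOST_SPAN:
                    host = candidate
                    break
        if host is not None:
            host_span = host.tx_end - host.tx_start
            exons = _nested_structure(rng, host_span - 2)
            length = exons[-1][1]
            offset = host.tx_start + int(rng.integers(1, host_span - length))
            chrom = host.chrom
        else:
            exons = _transcript_structure(rng, spec)
            length = exons[-1][1]
            names = [c for c, size in spec.chromosomes if size > length + 2]
            sizes = dict(spec.chromosomes)
            if not names:
                raise ValidationError(
                    "no chromosome is long enough for the requested transcripts"
                )
            chrom = names[int(rng.integers(0, len(names)))]
            offset = int(rng.integers(0, sizes[chrom] - length))
        placed = [(s + offset, e + offset) for s, e in exons]
        cds_start = cds_end = None
        if rng.random() < spec.cds_prob:
            cds_start, cds_end = _pick_cds(rng, placed)
        transcripts.append(
            Transcript(gid, tid, chrom, strand, placed[0][0], placed[-1][1],
                       tuple(placed), cds_start, cds_end)
        )
    if gtf_path is not None:
        from .formats import write_gtf

        write_gtf(transcripts, gtf_path)
    return transcripts


# ---------------------------------------------------------------------------
# signal
# ---------------------------------------------------------------------------

def _plant_peak(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    name: str,
    chrom: str,
    start: int,
    profile: SignalProfile,
) -> PlantedPeak:
    """Write one multimodal triangular peak into the profile.

    Anchor points — peak edges at the background depth, summits at their
    drawn heights, valleys at ``valley_depth_fraction * min`` of the
    flanking summits — are joined by straight lines, so the planted
    summits are the exact local maxima and the planted valleys the exact
    minima between them.
    """
    hw = spec.bump_halfwidth
    lo_k, hi_k = spec.summits_per_peak_range
    k = int(rng.integers(lo_k, hi_k + 1))
    lo_h, hi_h = spec.summit_height_range
    heights = rng.uniform(lo_h, hi_h, size=k)
    end = start + 2 * hw * k

    anchors: List[Tuple[int, float]] = [(start, spec.background_depth)]
    summits = []
    valleys = []
    for i in range(k):
        s = start + 2 * hw * i + hw
        anchors.append((s, float(heights[i])))
        summits.append((s, float(heights[i])))
        if i < k - 1:
            v_pos = start + 2 * hw * (i + 1)
            v_depth = spec.valley_depth_fraction * float(min(heights[i], heights[i + 1]))
            anchors.append((v_pos, v_depth))
            valleys.append((v_pos, v_depth))
    anchors.append((end - 1, spec.background_depth))

    for (p0, d0), (p1, d1) in zip(anchors, anchors[1:]):
        for pos in range(p0, p1):
            frac = (pos - p0) / (p1 - p0)
            profile.set_depth(chrom, pos, d0 + frac * (d1 - d0))
    profile.set_depth(chrom, end - 1, spec.background_depth)

    return PlantedPeak(name, chrom, start, end, tuple(summits), tuple(valleys))


def make_signal(
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    peaks_path=None,
    wig_path=None,
) -> Tuple[List[GenomicInterval], SignalProfile, List[PlantedPeak]]:
    """Generate peaks, their WIG-style signal, and the ground-truth table.

    Peaks are laid out left to right per chromosome with random gaps, so
    they never overlap.  Optionally writes the BED and WIG files.
    """
    if rng is None:
        rng = spec.rng()
    hw = spec.bump_halfwidth
    max_peak_len = 2 * hw * spec.summits_per_peak_range[1]
    sizes = dict(spec.chromosomes)
    cursors = {c: 0 for c, _ in spec.chromosomes}
    names = [c for c, _ in spec.chromosomes]

    profile = SignalProfile()
    truth: List[PlantedPeak] = []
    for i in range(spec.n_peaks):
        name = f"peak{i + 1}"
        order = rng.permutation(len(names))
        placed = False
        for idx in order:
            chrom = names[int(idx)]
            gap = int(rng.integers(500, 3001))
            start = cursors[chrom] + gap
            if start + max_peak_len >= sizes[chrom]:
                continue
            planted = _plant_peak(spec, rng, name, chrom, start, profile)
            cursors[chrom] = planted.end
            truth.append(planted)
            placed = True
            break
        if not placed:
            raise ValidationError(
                f"chromosomes exhausted after {len(truth)} peaks; "
                "reduce n_peaks or enlarge the genome"
            )

    truth.sort(key=lambda p: (p.chrom, p.start))
    peaks = [p.interval() for p in truth]
    if peaks_path is not None:
        from .formats import write_bed

        write_bed(peaks, peaks_path)
    if wig_path is not None:
        from .formats import write_wig

        write_wig(profile, wig_path)
    return peaks, profile, truth


def make_genome(
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    fasta_path=None,
) -> dict:
    """Random genome sequence per chromosome (uniform ACGT), optionally
    written as FASTA."""
    if rng is None:
        rng = spec.rng()
    genome = {
        chrom: "".join(_BASES[rng.integers(0, 4, size=length)])
        for chrom, length in spec.chromosomes
    }
    if fasta_path is not None:
        from .formats import write_fasta

        write_fasta(genome.items(), fasta_path)
    return genome


def write_truth_table(truth: Sequence[PlantedPeak], path) -> None:
    """Tab-separated ground-truth table: one row per planted peak."""
    with open(path, "w") as handle:
        handle.write("name\tchrom\tstart\tend\tsummits\theights\tvalleys\tvalley_depths\n")
        for p in truth:
            handle.write(
                "\t".join(
                    (
                        p.name,
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        ",".join(str(pos) for pos, _ in p.summits),
                        ",".join(f"{h:g}" for _, h in p.summits),
                        ",".join(str(pos) for pos, _ in p.valleys) or ".",
                        ",".join(f"{d:g}" for _, d in p.valleys) or ".",
                    )
                )
                + "\n"
            )
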