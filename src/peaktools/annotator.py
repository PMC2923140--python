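"""Annotation of peaks against gene models.

Two queries drive everything here:

* **NDG** (nearest downstream gene): for each peak, the closest
  non-overlapping gene whose transcription starts downstream of the
  peak, computed independently on each strand.  A forward-strand gene is
  downstream when its start lies at or beyond the peak end; a
  reverse-strand gene when its end lies at or before the peak start.
  Transcripts intersecting the peak by at least one base are reported
  separately with a gene-component classification, and a peak flanked by
  proximal downstream genes on both strands is flagged as a putative
  bidirectional promoter.

* **TSS** (nearest transcription start site): the transcript whose TSS
  minimizes the absolute distance to the peak's central base, with a
  signed distance that is positive when the peak center lies downstream
  of the TSS in the gene's transcription direction.

Both are implemented as pruned walks over the nested containment list
(:mod:`peaktools.nclist`): binary search locates the insertion point,
the walk expands outward, and subtrees are pruned using the fact that
every entry bounds the spans (hence the TSS positions) of everything
nested inside it.  Descending into sublists is what makes the walks
exact even when the best candidate is a gene nested inside another —
the answers are guaranteed to equal a full linear scan.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import pandas as pd

from .core import (
    FORWARD,
    REVERSE,
    GenomicInterval,
    PeaktoolsError,
    Transcript,
    ValidationError,
)
from .nclist import ContainmentIndex, Entry

# Gene-component kinds
FIVE_PRIME_UTR = "five_prime_utr"
THREE_PRIME_UTR = "three_prime_utr"
EXON_CDS = "exon_cds"
INTRON = "intron"
UPSTREAM = "upstream"
DOWNSTREAM = "downstream"


@dataclass(frozen=True)
class ComponentClass:
    """Where a position falls within a transcript's structure.

    ``intron_rank`` is 1-based in transcription order (rank 1 abuts the
    first exon of the transcript); ``n_introns`` is carried along so
    summaries can distinguish first / last / higher rank-order introns.
    """

    kind: str
    intron_rank: Optional[int] = None
    n_introns: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind == INTRON:
            if self.intron_rank is None or self.n_introns is None:
                raise ValidationError("intron classification requires rank and count")
            if not (1 <= self.intron_rank <= self.n_introns):
                raise ValidationError(
                    f"intron rank {self.intron_rank} outside [1, {self.n_introns}]"
                )
        elif self.intron_rank is not None:
            raise ValidationError(f"{self.kind} classification carries no intron rank")

    def __str__(self) -> str:
        if self.kind == INTRON:
            return f"intron_{self.intron_rank}"
        return self.kind


@dataclass(frozen=True)
class NDGResult:
    """Nearest downstream genes on both strands for one peak.

    Distances are gaps in bases (0 means adjacency); transcripts
    overlapping the peak never occupy the nearest slots.
    """

    peak: GenomicInterval
    overlapping: Tuple[Tuple[Transcript, ComponentClass], ...]
    nearest_forward: Optional[Tuple[Transcript, int]]
    nearest_reverse: Optional[Tuple[Transcript, int]]
    bidirectional_promoter: bool


@dataclass(frozen=True)
class TSSResult:
    """Nearest transcription start site for one peak.

    ``signed_distance`` is positive when the peak center lies downstream
    of the TSS in the transcript's direction of transcription, negative
    when upstream.  ``ties`` lists the transcript_ids of all equidistant
    transcripts (including the reported one) when there is more than one.
    """

    peak: GenomicInterval
    transcript: Optional[Transcript]
    signed_distance: Optional[int]
    within_gene: bool = False
    ties: Tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# overlap classification
# ---------------------------------------------------------------------------

def classify_overlap(peak: GenomicInterval, t: Transcript) -> ComponentClass:
    """Classify the peak's central base against a transcript's structure.

    The center maps to exactly one component: 5'/3' UTR (CDS required),
    CDS-containing exon, intron of a given rank in transcription order,
    or upstream/downstream of the transcript relative to its strand.
    Without an annotated CDS every exonic hit is reported as exon.
    """
    if peak.chrom != t.chrom:
        raise PeaktoolsError(
            f"peak on {peak.chrom} cannot be classified against transcript "
            f"{t.transcript_id} on {t.chrom}"
        )
    pos = peak.center
    forward = t.strand == FORWARD
    if pos < t.tx_start:
        return ComponentClass(UPSTREAM if forward else DOWNSTREAM)
    if pos >= t.tx_end:
        return ComponentClass(DOWNSTREAM if forward else UPSTREAM)

    for i, (ex_start, ex_end) in enumerate(t.exons):
        if ex_start <= pos < ex_end:
            if not t.has_cds:
                return ComponentClass(EXON_CDS)
            if pos < t.cds_start:
                return ComponentClass(FIVE_PRIME_UTR if forward else THREE_PRIME_UTR)
            if pos >= t.cds_end:
                return ComponentClass(THREE_PRIME_UTR if forward else FIVE_PRIME_UTR)
            return ComponentClass(EXON_CDS)
        if pos < ex_start:
            n = t.n_introns
            if i == 0:
                # transcript span extends before the exon hull (explicit
                # transcript feature): nearest structure is the 5'-most end
                if not n:
                    return ComponentClass(EXON_CDS)
                rank = 1 if forward else n
            else:
                genomic_rank = i  # intron before exon index i is genomic intron i
                rank = genomic_rank if forward else n - genomic_rank + 1
            return ComponentClass(INTRON, intron_rank=rank, n_introns=n)
    # inside the transcript span but beyond the last exon (possible when an
    # explicit transcript line extends past the exon hull): treat as intronic
    # only if introns exist, else fall back to exon classification
    if t.n_introns:
        rank = t.n_introns if forward else 1
        return ComponentClass(INTRON, intron_rank=rank, n_introns=t.n_introns)
    return ComponentClass(EXON_CDS)


# ---------------------------------------------------------------------------
# pruned NCList walks
# ---------------------------------------------------------------------------
# Pruning facts used below (valid at every level of the NCList):
#   * entries are sorted by start AND by end;
#   * everything nested under an entry lies within its span, so the
#     entry's span bounds starts, ends and TSS positions of its subtree.


def _best_forward(entries: Sequence[Entry], bound: int, best):
    """Min-start forward-strand entry with start > bound, descending into
    sublists.  ``best``/return value is (start, end, transcript_id, entry)."""
    starts = [e.start for e in entries]
    i = bisect_right(starts, bound)
    # suffix of the prefix: entries starting at or before bound whose span
    # still reaches past bound may hide nested candidates
    for j in range(i - 1, -1, -1):
        e = entries[j]
        if e.end - 1 <= bound:
            break  # ends only shrink leftwards: no nested start can exceed bound
        if e.children:
            best = _best_forward(e.children, bound, best)
    for e in entries[i:]:
        if best is not None and e.start > best[0]:
            break
        if e.strand == FORWARD:
            key = (e.start, e.end, e.payload.transcript_id, e)
            if best is None or key[:3] < best[:3]:
                best = key
        if e.children:
            best = _best_forward(e.children, bound, best)
    return best


def _best_reverse(entries: Sequence[Entry], bound: int, best):
    """Max-end reverse-strand entry with end <= bound, descending into
    sublists.  ``best`` is (-end, start, transcript_id, entry)."""
    starts = [e.start for e in entries]
    i = bisect_left(starts, bound)  # eligible entries satisfy start < end <= bound
    for j in range(i - 1, -1, -1):
        e = entries[j]
        if best is not None and e.end < -best[0]:
            break  # subtree ends are <= e.end: cannot beat or tie best
        if e.end <= bound and e.strand == REVERSE:
            key = (-e.end, e.start, e.payload.transcript_id, e)
            if best is None or key[:3] < best[:3]:
                best = key
        if e.children:
            best = _best_reverse(e.children, bound, best)
    return best


def nearest_downstream_genes(
    peak: GenomicInterval,
    index: ContainmentIndex,
    bidir_window: int = 1000,
) -> NDGResult:
    """Nearest non-overlapping downstream gene on each strand, plus all
    transcripts overlapping the peak with their component classification.

    ``bidir_window``: when both downstream genes exist within this many
    bases the peak is flagged as a putative bidirectional promoter.
    A chromosome absent from the annotation yields all-none slots.
    """
    overlapping = tuple(
        (e.payload, classify_overlap(peak, e.payload))
        for e in index.overlapping(peak.chrom, peak.start, peak.end)
    )

    primaries = index.primaries(peak.chrom)
    nearest_forward = nearest_reverse = None
    if primaries:
        fwd = _best_forward(primaries, peak.end - 1, None)
        if fwd is not None:
            t = fwd[3].payload
            nearest_forward = (t, t.tx_start - peak.end)
        rev = _best_reverse(primaries, peak.start, None)
        if rev is not None:
            t = rev[3].payload
            nearest_reverse = (t, peak.start - t.tx_end)

    bidirectional = (
        nearest_forward is not None
        and nearest_reverse is not None
        and nearest_forward[1] <= bidir_window
        and nearest_reverse[1] <= bidir_window
    )
    return NDGResult(peak, overlapping, nearest_forward, nearest_reverse, bidirectional)


def _tss_distance(entry: Entry, center: int) -> int:
    return abs(entry.payload.tss - center)


def _best_tss(entries: Sequence[Entry], center: int, best):
    """Min |TSS - center| entry; ``best`` is (distance, transcript_id, entry).

    Branch-and-bound: a subtree rooted at ``e`` only holds TSS positions
    inside ``[e.start, e.end)``, giving a lower bound on the distance.
    """
    starts = [e.start for e in entries]
    i = bisect_right(starts, center)
    for e in entries[i:]:  # spans strictly right of center
        if best is not None and e.start - center > best[0]:
            break
        best = _consider_tss(e, center, best)
        if e.children:
            best = _best_tss(e.children, center, best)
    for j in range(i - 1, -1, -1):  # spans starting at or before center
        e = entries[j]
        if e.end <= center:
            lower = center - (e.end - 1)
            if best is not None and lower > best[0]:
                break  # ends shrink leftwards, bound only grows
        best = _consider_tss(e, center, best)
        if e.children:
            best = _best_tss(e.children, center, best)
    return best


def _consider_tss(entry: Entry, center: int, best):
    key = (_tss_distance(entry, center), entry.payload.transcript_id, entry)
    if best is None or key[:2] < best[:2]:
        return key
    return best


def _collect_tss_at(entries: Sequence[Entry], center: int, distance: int,
                    out: List[Entry]) -> None:
    """All entries with |TSS - center| == distance (for tie reporting)."""
    for e in entries:
        if e.start - center > distance:
            break
        if not (e.end <= center and center - (e.end - 1) > distance):
            if _tss_distance(e, center) == distance:
                out.append(e)
            if e.children:
                _collect_tss_at(e.children, center, distance, out)


def nearest_tss(peak: GenomicInterval, index: ContainmentIndex) -> TSSResult:
    """Transcript whose TSS is closest to the peak's central base.

    Ties on the absolute distance are broken toward the lexicographically
    smallest transcript_id and all tied ids are reported.  A chromosome
    with no transcripts yields a none-result.
    """
    center = peak.center
    primaries = index.primaries(peak.chrom)
    if not primaries:
        return TSSResult(peak, None, None)
    best = _best_tss(primaries, center, None)
    distance, _tid, entry = best
    t: Transcript = entry.payload
    signed = center - t.tss if t.strand == FORWARD else t.tss - center
    ties: Tuple[str, ...] = ()
    tied_entries: List[Entry] = []
    _collect_tss_at(primaries, center, distance, tied_entries)
    if len(tied_entries) > 1:
        ties = tuple(sorted(e.payload.transcript_id for e in tied_entries))
    within = t.tx_start <= center < t.tx_end
    return TSSResult(peak, t, signed, within, ties)


# ---------------------------------------------------------------------------
# profiling summaries
# ---------------------------------------------------------------------------

def _distance_bin_labels(edges: Sequence[int]) -> List[str]:
    labels = []
    for lo, hi in zip(edges, edges[1:]):
        labels.append(f"{lo / 1000:g}-{hi / 1000:g} kb")
    labels.append(f">{edges[-1] / 1000:g} kb")
    return labels


def profile_distances(
    results: Sequence[Union[TSSResult, int, float]],
    edges: Sequence[int] = (0, 1000, 10000),
) -> pd.DataFrame:
    """Tabulate TSS distances into labeled upstream/downstream bins.

    ``edges`` must be sorted non-negative distances starting at 0; the
    default bins match the promoter-proximal (up to 1 kb) versus distal
    (beyond 10 kb) cutoffs used in genome-wide binding-site profiling.
    Peaks whose center lies inside the assigned gene are counted in a
    separate "within gene" bin.  Returns a DataFrame with columns
    ``bin``, ``count``, ``percentage`` (percentages sum to 100 up to
    rounding, or all zero on empty input).
    """
    edges = list(edges)
    if edges != sorted(edges) or len(set(edges)) != len(edges):
        raise PeaktoolsError("bin edges must be strictly increasing")
    if not edges or edges[0] != 0:
        raise PeaktoolsError("bin edges must start at 0")

    side_labels = _distance_bin_labels(edges)
    bins = (
        ["within gene"]
        + [f"downstream {lab}" for lab in side_labels]
        + [f"upstream {lab}" for lab in side_labels]
    )
    counts = {b: 0 for b in bins}

    def bin_of(distance: float, within: bool) -> str:
        if within:
            return "within gene"
        side = "downstream" if distance >= 0 else "upstream"
        d = abs(distance)
        for (lo, hi), lab in zip(zip(edges, edges[1:]), side_labels):
            in_bin = (lo <= d <= hi) if lo == 0 else (lo < d <= hi)
            if in_bin:
                return f"{side} {lab}"
        return f"{side} {side_labels[-1]}"

    total = 0
    for r in results:
        if isinstance(r, TSSResult):
            if r.signed_distance is None:
                continue
            counts[bin_of(r.signed_distance, r.within_gene)] += 1
        else:
            counts[bin_of(float(r), False)] += 1
        total += 1

    rows = [
        {
            "bin": b,
            "count": counts[b],
            "percentage": (100.0 * counts[b] / total) if total else 0.0,
        }
        for b in bins
    ]
    return pd.DataFrame(rows, columns=["bin", "count", "percentage"])


_COMPONENT_ORDER = [
    "5' UTR",
    "exon (CDS)",
    "first intron",
    "higher rank-order introns",
    "last intron",
    "3' UTR",
    "upstream",
    "downstream",
]


def component_category(c: ComponentClass) -> str:
    """Collapse a classification into the summary categories used for
    within-gene binding-site composition plots."""
    if c.kind == FIVE_PRIME_UTR:
        return "5' UTR"
    if c.kind == THREE_PRIME_UTR:
        return "3' UTR"
    if c.kind == EXON_CDS:
        return "exon (CDS)"
    if c.kind == UPSTREAM:
        return "upstream"
    if c.kind == DOWNSTREAM:
        return "downstream"
    if c.intron_rank == 1:
        return "first intron"
    if c.n_introns is not None and c.intron_rank == c.n_introns:
        return "last intron"
    return "higher rank-order introns"


def profile_components(classes: Sequence[ComponentClass]) -> pd.DataFrame:
    """Tabulate component classifications into the standard categories
    (UTRs, CDS exons, first / last / higher rank-order introns).  Counts
    conserve the input size; single-intron transcripts count as first
    intron."""
    counts = {cat: 0 for cat in _COMPONENT_ORDER}
    for c in classes:
        counts[component_category(c)] += 1
    total = len(classes)
    rows = [
        {
            "component": cat,
            "count": counts[cat],
            "percentage": (100.0 * counts[cat] / total) if total else 0.0,
        }
        for cat in _COMPONENT_ORDER
        if counts[cat] or cat not in ("upstream", "downstream")
    ]
    return pd.DataFrame(rows, columns=["component", "count", "percentage"])


def annotate_ndg(
    peaks: Sequence[GenomicInterval],
    transcripts: Sequence[Transcript],
    bidir_window: int = 1000,
) -> List[NDGResult]:
    """Run the NDG query for every peak against one shared index."""
    index = ContainmentIndex.build(transcripts)
    return [nearest_downstream_genes(p, index, bidir_window) for p in peaks]


def annotate_tss(
    peaks: Sequence[GenomicInterval],
    transcripts: Sequence[Transcript],
) -> List[TSSResult]:
    """Run the TSS query for every peak against one shared index."""
    index = ContainmentIndex.build(transcripts)
    return [nearest_tss(p, index) for p in peaks]
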