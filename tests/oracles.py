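"""Independent brute-force reference implementations used to verify the
library.  Everything here is written directly from first principles
(exhaustive scans, all-pairs tests) and shares no code with the package.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple


# ---------------------------------------------------------------------------
# splitter oracles
# ---------------------------------------------------------------------------

def brute_local_maxima(depths: Sequence[float]) -> List[Tuple[int, float]]:
    """Positions whose depth exceeds the nearest differing depth on each
    side (plateaus at their leftmost offset), directly from the definition."""
    n = len(depths)
    maxima = []
    for p in range(n):
        if depths[p] <= 0:
            continue
        if p > 0 and depths[p - 1] == depths[p]:
            continue  # not the leftmost base of its plateau
        left = p - 1
        while left >= 0 and depths[left] == depths[p]:
            left -= 1
        if left >= 0 and depths[left] > depths[p]:
            continue
        right = p + 1
        while right < n and depths[right] == depths[p]:
            right += 1
        if right < n and depths[right] > depths[p]:
            continue
        maxima.append((p, float(depths[p])))
    return maxima


def brute_split_boundaries(depths: Sequence[float], valley_factor: float) -> List[int]:
    """Cut offsets by testing every valley between every adjacent maxima
    pair explicitly."""
    maxima = brute_local_maxima(depths)
    cuts = []
    for (o1, h1), (o2, h2) in zip(maxima, maxima[1:]):
        between = [(depths[p], p) for p in range(o1 + 1, o2)]
        if not between:
            continue
        vmin = min(d for d, _ in between)
        if vmin < valley_factor * min(h1, h2):
            cut = min(p for d, p in between if d == vmin)
            cuts.append(cut)
    return cuts


# ---------------------------------------------------------------------------
# containment / annotation oracles (linear and quadratic scans)
# ---------------------------------------------------------------------------

def brute_containers(intervals, i: int) -> List[int]:
    """Indices j such that interval j strictly houses interval i
    (same chrom, j.start <= i.start, i.end <= j.end, j != i), by the
    exactly-one-home tie convention: among identical spans the earlier
    interval contains the later."""
    target = intervals[i]
    out = []
    for j, other in enumerate(intervals):
        if j == i or other.chrom != target.chrom:
            continue
        if other.start <= target.start and target.end <= other.end:
            same_span = (other.start, other.end) == (target.start, target.end)
            if same_span and j > i:
                continue
            out.append(j)
    return out


def brute_first_start_after(intervals, chrom: str, pos: int):
    """Among intervals NOT contained in any other (primary), the one with
    the smallest start > pos."""
    best = None
    for i, iv in enumerate(intervals):
        if iv.chrom != chrom or iv.start <= pos:
            continue
        if brute_containers(intervals, i):
            continue
        if best is None or iv.start < best.start:
            best = iv
    return best


def brute_overlapping_transcripts(peak, transcripts):
    return [
        t for t in transcripts
        if t.chrom == peak.chrom and t.tx_start < peak.end and peak.start < t.tx_end
    ]


def brute_ndg(peak, transcripts):
    """(nearest_forward, nearest_reverse, overlapping) by full linear scan.

    Forward: + transcript with tx_start >= peak.end minimizing
    (tx_start, tx_end, transcript_id).  Reverse: - transcript with
    tx_end <= peak.start maximizing tx_end (ties by smaller start, then id).
    """
    fwd = rev = None
    for t in transcripts:
        if t.chrom != peak.chrom:
            continue
        if t.strand == "+" and t.tx_start >= peak.end:
            key = (t.tx_start, t.tx_end, t.transcript_id)
            if fwd is None or key < fwd[0]:
                fwd = (key, t)
        if t.strand == "-" and t.tx_end <= peak.start:
            key = (-t.tx_end, t.tx_start, t.transcript_id)
            if rev is None or key < rev[0]:
                rev = (key, t)
    nearest_forward = (fwd[1], fwd[1].tx_start - peak.end) if fwd else None
    nearest_reverse = (rev[1], peak.start - rev[1].tx_end) if rev else None
    return nearest_forward, nearest_reverse, brute_overlapping_transcripts(peak, transcripts)


def brute_tss(peak, transcripts):
    """(transcript, signed_distance, tied ids) by exhaustive scan over all
    transcripts on the peak's chromosome."""
    center = (peak.start + peak.end - 1) // 2
    candidates = [t for t in transcripts if t.chrom == peak.chrom]
    if not candidates:
        return None, None, ()
    best = min(candidates, key=lambda t: (abs(t.tss - center), t.transcript_id))
    dist = abs(best.tss - center)
    signed = center - best.tss if best.strand == "+" else best.tss - center
    tied = sorted(t.transcript_id for t in candidates if abs(t.tss - center) == dist)
    ties = tuple(tied) if len(tied) > 1 else ()
    return best, signed, ties


# ---------------------------------------------------------------------------
# overlap oracles
# ---------------------------------------------------------------------------

def brute_overlap_pairs(S1, S2):
    """All intersecting (i, j) index pairs by the quadratic all-pairs test."""
    return [
        (i, j)
        for i, a in enumerate(S1)
        for j, b in enumerate(S2)
        if a.chrom == b.chrom and a.start < b.end and b.start < a.end
    ]


def sweep_merge(datasets):
    """Sweep-line union: returns [(chrom, start, end, member frozenset)]."""
    events = sorted(
        (iv.chrom, iv.start, iv.end, ds)
        for ds, dataset in enumerate(datasets)
        for iv in dataset
    )
    merged = []
    cur: Optional[list] = None
    for chrom, start, end, ds in events:
        if cur and cur[0] == chrom and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(ds)
        else:
            if cur:
                merged.append((cur[0], cur[1], cur[2], frozenset(cur[3])))
            cur = [chrom, start, end, {ds}]
    if cur:
        merged.append((cur[0], cur[1], cur[2], frozenset(cur[3])))
    return merged


def covered_bases(intervals, chrom: str, length: int) -> List[bool]:
    """Base-level bitmap of coverage on one chromosome (for small genomes)."""
    mask = [False] * length
    for iv in intervals:
        if iv.chrom == chrom:
            for p in range(iv.start, min(iv.end, length)):
                mask[p] = True
    return mask
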