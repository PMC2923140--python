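"""Subdivision of multimodal enrichment peaks into discrete subpeaks.

Peak callers merge adjacent areas of enrichment, so one reported peak
often covers several binding events.  The splitter scans the per-base
read depth inside each peak for local maxima and cuts between two
adjacent maxima whenever the valley between them dips below
``valley_factor * min(height_left, height_right)``.  Summits of the
resulting subpeaks localize the underlying binding sites and seed the
sequence windows used for motif discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    ChromSizes,
    GenomicInterval,
    PeaktoolsError,
    SignalProfile,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitterConfig:
    """Tunable parameters of the subpeak division rule.

    valley_factor
        Multiplier in (0, 1] applied to the lower of two adjacent maxima;
        the valley between them must dip below the product for a cut.
        Higher values split more readily.
    min_height
        Subpeaks whose summit depth falls below this are dropped after
        splitting (0 keeps everything).
    summit_flank
        Bases kept on each side of a summit when emitting sequence
        windows for motif discovery.
    """

    valley_factor: float = 0.6
    min_height: float = 0.0
    summit_flank: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.valley_factor <= 1.0):
            raise ValidationError(
                f"valley_factor must be in (0, 1], got {self.valley_factor}"
            )
        if self.min_height < 0:
            raise ValidationError("min_height must be non-negative")
        if self.summit_flank < 0:
            raise ValidationError("summit_flank must be non-negative")


@dataclass(frozen=True)
class Subpeak:
    """A split product: one putative binding locus inside a parent peak."""

    parent_id: str
    interval: GenomicInterval
    summit: int
    height: float

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValidationError("summit outside subpeak boundaries")


def find_local_maxima(depths: Sequence[float]) -> List[Tuple[int, float]]:
    """Local maxima of a dense depth vector, one per maximal plateau.

    A position is a maximum when its depth is greater than the nearest
    differing depth on each side (boundary positions compare only
    inward); plateaus are represented at their leftmost offset.
    Zero-depth positions never count, so an all-zero vector yields no
    maxima.
    """
    d = np.asarray(depths, dtype=float)
    n = d.size
    if n == 0:
        raise ValidationError("depth vector is empty")
    maxima: List[Tuple[int, float]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and d[j + 1] == d[i]:
            j += 1
        left_ok = i == 0 or d[i - 1] < d[i]
        right_ok = j == n - 1 or d[j + 1] < d[i]
        if left_ok and right_ok and d[i] > 0:
            maxima.append((i, float(d[i])))
        i = j + 1
    return maxima


def _cut_offsets(
    depths: np.ndarray,
    maxima: Sequence[Tuple[int, float]],
    valley_factor: float,
) -> List[int]:
    """Offsets at which the peak is divided (valley base goes rightward)."""
    cuts: List[int] = []
    for (o1, h1), (o2, h2) in zip(maxima, maxima[1:]):
        if o2 - o1 < 2:
            continue  # no open interval between adjacent offsets
        valley = depths[o1 + 1:o2]
        vmin = valley.min()
        threshold = valley_factor * min(h1, h2)
        if vmin < threshold:
            cuts.append(o1 + 1 + int(np.argmin(valley)))  # leftmost deepest base
    return cuts


def split_peak(
    peak: GenomicInterval,
    signal: SignalProfile,
    cfg: SplitterConfig = SplitterConfig(),
    parent_id: Optional[str] = None,
) -> List[Subpeak]:
    """Divide one peak into subpeaks by the relative-local-maxima rule.

    Adjacent maxima are compared pairwise left to right; a cut is placed
    at the leftmost deepest base of any qualifying valley, with the
    valley base assigned to the right-hand subpeak.  Before min_height
    filtering the subpeaks tile the parent exactly.  A peak with no
    positive coverage yields an empty list (with a logged warning), not
    an error.
    """
    if parent_id is None:
        parent_id = peak.name if peak.name is not None else "peak"
    depths = signal.profile(peak.chrom, peak.start, peak.end)
    maxima = find_local_maxima(depths)
    if not maxima:
        logger.warning(
            "peak %s %s:%d-%d has no signal coverage; skipped",
            parent_id, peak.chrom, peak.start, peak.end,
        )
        return []

    cuts = _cut_offsets(depths, maxima, cfg.valley_factor)
    boundaries = [0] + cuts + [len(depths)]
    subpeaks: List[Subpeak] = []
    for lo, hi in zip(boundaries, boundaries[1:]):
        segment = depths[lo:hi]
        summit_offset = lo + int(np.argmax(segment))
        height = float(segment.max())
        interval = GenomicInterval(
            peak.chrom, peak.start + lo, peak.start + hi, name=parent_id
        )
        subpeaks.append(
            Subpeak(parent_id, interval, peak.start + summit_offset, height)
        )
    return [sp for sp in subpeaks if sp.height >= cfg.min_height]


def split_all(
    peaks: Sequence[GenomicInterval],
    signal: SignalProfile,
    cfg: SplitterConfig = SplitterConfig(),
) -> List[Subpeak]:
    """Split every peak; parent ids default to the peak name or its ordinal.

    Output is sorted by (chromosome, start).
    """
    out: List[Subpeak] = []
    for ordinal, peak in enumerate(peaks, start=1):
        pid = peak.name if peak.name is not None else str(ordinal)
        out.extend(split_peak(peak, signal, cfg, parent_id=pid))
    out.sort(key=lambda sp: (sp.interval.chrom, sp.interval.start, sp.interval.end))
    return out


def summit_windows(
    subpeaks: Sequence[Subpeak],
    cfg: SplitterConfig,
    sizes: ChromSizes,
) -> List[GenomicInterval]:
    """Sequence windows of ``summit_flank`` bases each side of every summit,
    clipped to chromosome bounds.  Window names are ``parent_id/ordinal``
    with ordinals counted per parent."""
    windows: List[GenomicInterval] = []
    counters: dict = {}
    for sp in subpeaks:
        chrom = sp.interval.chrom
        length = sizes.get(chrom)
        if length is None:
            raise PeaktoolsError(f"chromosome {chrom!r} missing from sizes table")
        if sp.summit >= length:
            raise PeaktoolsError(
                f"summit {chrom}:{sp.summit} beyond chromosome length {length}"
            )
        ordinal = counters.get(sp.parent_id, 0) + 1
        counters[sp.parent_id] = ordinal
        start = max(sp.summit - cfg.summit_flank, 0)
        end = min(sp.summit + cfg.summit_flank + 1, length)
        windows.append(
            GenomicInterval(chrom, start, end, name=f"{sp.parent_id}/{ordinal}")
        )
    return windows
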