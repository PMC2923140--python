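"""Core domain types shared by every peaktools module.

All coordinates are 0-based half-open (``[start, end)``) on a named
chromosome.  File formats that use other conventions (GTF, WIG) are
converted at the parser boundary in :mod:`peaktools.formats`, so nothing
outside that module ever sees a 1-based coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Tuple

import numpy as np

FORWARD = "+"
REVERSE = "-"
UNSTRANDED = "."

_STRANDS = frozenset((FORWARD, REVERSE, UNSTRANDED))


class PeaktoolsError(Exception):
    """Base class for all errors raised by peaktools."""


class ParseError(PeaktoolsError, ValueError):
    """A malformed record in an input file.

    Carries the offending line number when known so CLI users can locate
    the problem without a stack trace.
    """

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(PeaktoolsError, ValueError):
    """A domain object violating its invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on a chromosome.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded); ``name`` and
    ``score`` are optional annotations carried through from BED columns
    4 and 5.
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name is empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end (empty intervals rejected)"
            )
        if self.strand not in _STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Central base; even-length intervals take the left-of-center base."""
        return (self.start + self.end - 1) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share at least one base (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class Transcript:
    """A gene model: stranded transcript span with ordered exons and
    an optional CDS span from which UTRs are inferred.

    ``exons`` are non-overlapping ``(start, end)`` pairs sorted by start,
    all within ``[tx_start, tx_end)``.  The TSS is ``tx_start`` on the
    forward strand and ``tx_end - 1`` on the reverse strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: Tuple[Tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be + or -, "
                f"got {self.strand!r}"
            )
        if not (0 <= self.tx_start < self.tx_end):
            raise ValidationError(
                f"transcript {self.transcript_id}: invalid span "
                f"[{self.tx_start}, {self.tx_end})"
            )
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        prev_end = None
        for start, end in self.exons:
            if not (self.tx_start <= start < end <= self.tx_end):
                raise ValidationError(
                    f"transcript {self.transcript_id}: exon [{start}, {end}) "
                    f"outside transcript span"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError(
                f"transcript {self.transcript_id}: CDS start/end must both be set"
            )
        if self.cds_start is not None:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise ValidationError(
                    f"transcript {self.transcript_id}: CDS outside transcript span"
                )

    @property
    def tss(self) -> int:
        """Transcription start site (0-based base position)."""
        return self.tx_start if self.strand == FORWARD else self.tx_end - 1

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    @property
    def n_introns(self) -> int:
        return max(len(self.exons) - 1, 0)

    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.tx_start, self.tx_end, self.strand, self.transcript_id
        )


# A ChromSizes table is a plain mapping chromosome name -> length.
ChromSizes = Mapping[str, int]


def infer_chrom_sizes(*collections: Iterable) -> dict:
    """Derive a chromosome-sizes table from loaded intervals/transcripts.

    Length is the maximum end coordinate observed per chromosome across
    all the given collections (intervals, subpeaks or transcripts).
    """
    sizes: dict = {}
    for coll in collections:
        for item in coll:
            if isinstance(item, Transcript):
                chrom, end = item.chrom, item.tx_end
            else:
                chrom, end = item.chrom, item.end
            if end > sizes.get(chrom, 0):
                sizes[chrom] = end
    return sizes


class SignalProfile:
    """Per-base read depth reconstructed from a WIG track.

    Stores a sparse position -> depth map per chromosome; querying any
    interval yields a dense vector with 0.0 at uncovered bases.  Depths
    are floats so tiling-array fluorescence tracks work as well as
    integral read counts.
    """

    def __init__(self) -> None:
        self._depths: dict = {}

    def set_depth(self, chrom: str, pos: int, depth: float) -> bool:
        """Record depth at one base.  Returns True when overwriting an
        existing value (the caller decides whether to warn)."""
        if depth < 0:
            raise ValidationError(f"negative depth {depth} at {chrom}:{pos}")
        per_chrom = self._depths.setdefault(chrom, {})
        clash = pos in per_chrom
        per_chrom[pos] = float(depth)
        return clash

    def chromosomes(self) -> list:
        return sorted(self._depths)

    def positions(self, chrom: str) -> list:
        """Sorted covered positions on a chromosome."""
        return sorted(self._depths.get(chrom, ()))

    def depth_at(self, chrom: str, pos: int) -> float:
        return self._depths.get(chrom, {}).get(pos, 0.0)

    def profile(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense depth vector over ``[start, end)`` (zeros where uncovered)."""
        if end <= start:
            raise ValidationError(f"empty query interval [{start}, {end})")
        out = np.zeros(end - start, dtype=float)
        per_chrom = self._depths.get(chrom)
        if not per_chrom:
            return out
        if len(per_chrom) < (end - start):
            for pos, depth in per_chrom.items():
                if start <= pos < end:
                    out[pos - start] = depth
        else:
            for pos in range(start, end):
                d = per_chrom.get(pos)
                if d is not None:
                    out[pos - start] = d
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalProfile):
            return NotImplemented
        return self._depths == other._depths

    def __repr__(self) -> str:
        n = sum(len(v) for v in self._depths.values())
        return f"SignalProfile({len(self._depths)} chromosomes, {n} covered bases)"
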