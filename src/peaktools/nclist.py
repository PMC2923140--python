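"""Nested containment list (NCList) index over genomic intervals.

A plain start-sorted interval list does not keep end positions sorted
when some intervals are nested inside others (overlapping genes are
common in higher eukaryotes), which breaks binary search on either
coordinate.  The NCList fixes this by moving every interval that is
contained in another into a per-container sublist: the remaining
*primary* list is sorted by start **and** by end simultaneously, so all
positional queries reduce to binary search plus short pruned walks.
Sublists are themselves NCLists, recursively, so the same property
holds at every level.

This index is the workhorse behind the nearest-downstream-gene, TSS and
dataset-overlap queries in :mod:`peaktools.annotator` and
:mod:`peaktools.overlap`.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from typing import Callable, Iterable, Iterator, List, Optional, Sequence

from .core import GenomicInterval, PeaktoolsError, Transcript


class Entry:
    """One indexed interval plus its payload and containment links."""

    __slots__ = ("interval", "payload", "parent", "children", "_owner")

    def __init__(self, interval: GenomicInterval, payload) -> None:
        self.interval = interval
        self.payload = payload
        self.parent: Optional["Entry"] = None
        self.children: List["Entry"] = []
        self._owner: Optional["ContainmentIndex"] = None

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    def __repr__(self) -> str:
        return (
            f"Entry({self.chrom}:{self.start}-{self.end}/{self.interval.strand}, "
            f"{len(self.children)} contained)"
        )


class ContainmentIndex:
    """Per-chromosome NCList over intervals with payloads.

    Build is O(n log n): sort by (start ascending, end descending, input
    order) and assign containment in a single stack pass.  Identical
    spans keep the first-encountered interval primary; later duplicates
    land in its sublist, so every input interval has exactly one home.
    """

    def __init__(self, entries_by_chrom: dict) -> None:
        self._primary = entries_by_chrom
        self._starts = {
            chrom: [e.start for e in entries]
            for chrom, entries in entries_by_chrom.items()
        }
        self._ends = {
            chrom: [e.end for e in entries]
            for chrom, entries in entries_by_chrom.items()
        }
        for entries in entries_by_chrom.values():
            stack = list(entries)
            while stack:
                e = stack.pop()
                e._owner = self
                stack.extend(e.children)

    # -- construction -------------------------------------------------------

    @classmethod
    def build(
        cls,
        items: Iterable,
        interval_of: Optional[Callable] = None,
    ) -> "ContainmentIndex":
        """Index an iterable of intervals, transcripts or arbitrary payloads.

        ``interval_of`` maps a payload to its :class:`GenomicInterval`;
        by default intervals index themselves and transcripts are
        indexed by their transcript span.
        """
        if interval_of is None:
            def interval_of(item):
                if isinstance(item, Transcript):
                    return item.interval()
                return item

        decorated = []
        for order, item in enumerate(items):
            iv = interval_of(item)
            decorated.append((iv.chrom, iv.start, -iv.end, order, Entry(iv, item)))
        decorated.sort(key=lambda rec: rec[:4])

        by_chrom: dict = {}
        stack: List[Entry] = []
        current_chrom = None
        for chrom, _start, _neg_end, _order, entry in decorated:
            if chrom != current_chrom:
                stack = []
                current_chrom = chrom
            while stack and stack[-1].end < entry.end:
                stack.pop()
            # identical spans: the earlier twin is still on the stack and
            # becomes the container (end == entry.end, start <= entry.start)
            if stack:
                parent = stack[-1]
                entry.parent = parent
                parent.children.append(entry)
            else:
                by_chrom.setdefault(chrom, []).append(entry)
            stack.append(entry)
        return cls(by_chrom)

    # -- introspection ------------------------------------------------------

    def chromosomes(self) -> list:
        return sorted(self._primary)

    def primaries(self, chrom: str) -> Sequence[Entry]:
        return self._primary.get(chrom, ())

    def __iter__(self) -> Iterator[Entry]:
        """All entries (primary and nested), depth-first per chromosome."""
        for chrom in self.chromosomes():
            stack = list(reversed(self._primary[chrom]))
            while stack:
                entry = stack.pop()
                yield entry
                stack.extend(reversed(entry.children))

    def __len__(self) -> int:
        return sum(1 for _ in self)

    # -- primitive queries --------------------------------------------------

    def first_start_after(self, chrom: str, pos: int) -> Optional[Entry]:
        """The primary entry with the smallest start strictly greater than
        ``pos``, or None.  Unknown chromosomes yield None, not an error."""
        entries = self._primary.get(chrom)
        if not entries:
            return None
        i = bisect_right(self._starts[chrom], pos)
        return entries[i] if i < len(entries) else None

    def last_start_before(self, chrom: str, pos: int) -> Optional[Entry]:
        """The primary entry with the largest start strictly less than ``pos``."""
        entries = self._primary.get(chrom)
        if not entries:
            return None
        i = bisect_left(self._starts[chrom], pos)
        return entries[i - 1] if i > 0 else None

    def containers_of(self, entry: Entry) -> List[Entry]:
        """The chain of entries whose spans contain ``entry``, innermost first."""
        if entry._owner is not self:
            raise PeaktoolsError("entry does not belong to this index")
        chain: List[Entry] = []
        node = entry.parent
        while node is not None:
            chain.append(node)
            node = node.parent
        return chain

    def overlapping(self, chrom: str, start: int, end: int) -> List[Entry]:
        """All entries (any depth) intersecting ``[start, end)`` by >= 1 base.

        Classic NCList query: at each level ends are sorted, so binary
        search finds the first possible intersector and the start-sorted
        walk stops at the first entry beyond the query.
        """
        hits: List[Entry] = []
        entries = self._primary.get(chrom)
        if entries:
            self._overlap_level(entries, self._ends[chrom], start, end, hits)
        return hits

    def has_overlap(self, chrom: str, start: int, end: int) -> bool:
        """Whether any indexed interval intersects ``[start, end)``.

        Only the primary level needs checking: a nested interval's
        container spans it, so the container intersects whenever the
        nested interval does.  O(log n).
        """
        entries = self._primary.get(chrom)
        if not entries:
            return False
        i = bisect_right(self._ends[chrom], start)
        return i < len(entries) and entries[i].start < end

    def _overlap_level(
        self,
        entries: Sequence[Entry],
        ends: Sequence[int],
        start: int,
        end: int,
        hits: List[Entry],
    ) -> None:
        i = bisect_right(ends, start)  # first entry with end > start
        for e in entries[i:]:
            if e.start >= end:
                break
            hits.append(e)
            if e.children:
                self._overlap_level(
                    e.children, [c.end for c in e.children], start, end, hits
                )
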