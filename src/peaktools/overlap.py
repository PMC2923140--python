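"""Inter-dataset overlap: pairwise intersection, non-redundant unions,
and a Monte-Carlo enrichment P-value.

Two peak sets S1 and S2 overlap wherever loci intersect by at least one
nucleotide (strand is ignored throughout).  Statistical enrichment is
assessed by repeatedly redrawing S1 under a null that preserves each
peak's chromosome and length but places its start uniformly at random,
and counting how often the randomized sets overlap S2 at least as much
as the real one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import ChromSizes, GenomicInterval, PeaktoolsError, ValidationError
from .nclist import ContainmentIndex


@dataclass(frozen=True)
class OverlapReport:
    """Pairs of intersecting loci between two peak sets.

    ``n1_hit`` / ``n2_hit`` count intervals of each set with at least one
    partner in the other.
    """

    pairs: Tuple[Tuple[GenomicInterval, GenomicInterval], ...]
    n1_hit: int
    n2_hit: int
    n1: int
    n2: int

    @property
    def fraction_s1_hit(self) -> float:
        return self.n1_hit / self.n1 if self.n1 else 0.0


@dataclass(frozen=True)
class RandomizationConfig:
    """Parameters of the Monte-Carlo null for overlap enrichment.

    ``iterations`` randomized datasets are drawn (default 1000, making
    the smallest reportable p-value 1/1001); ``sizes`` supplies the
    chromosome lengths that bound random placements.
    """

    sizes: ChromSizes
    iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")


def overlap_pairs(
    S1: Sequence[GenomicInterval],
    S2: Sequence[GenomicInterval],
) -> OverlapReport:
    """All (L1, L2) pairs intersecting by >= 1 base, strand-blind.

    S2 is indexed as an NCList once; each L1 is answered by binary search
    plus a bounded walk that also visits containment sublists, so nested
    S2 intervals spanning L1 are found.
    """
    index = ContainmentIndex.build(S2)
    pairs: List[Tuple[GenomicInterval, GenomicInterval]] = []
    hit2: set = set()
    n1_hit = 0
    for L1 in S1:
        entries = index.overlapping(L1.chrom, L1.start, L1.end)
        if entries:
            n1_hit += 1
        for e in entries:
            pairs.append((L1, e.payload))
            hit2.add(id(e.payload))
    return OverlapReport(tuple(pairs), n1_hit, len(hit2), len(S1), len(S2))


def _count_hits(S1: Sequence[GenomicInterval], index: ContainmentIndex) -> int:
    """Number of S1 intervals with >= 1 intersector in the indexed set."""
    count = 0
    for L1 in S1:
        if index.has_overlap(L1.chrom, L1.start, L1.end):
            count += 1
    return count


def _count_hits_raw(triples, index: ContainmentIndex) -> int:
    """As _count_hits but over (chrom, start, end) triples."""
    count = 0
    for chrom, start, end in triples:
        if index.has_overlap(chrom, start, end):
            count += 1
    return count


def merge_union(
    datasets: Sequence[Sequence[GenomicInterval]],
) -> List[Tuple[GenomicInterval, Tuple[bool, ...]]]:
    """Non-redundant union of several peak sets.

    Intervals from all datasets are merged wherever they intersect by at
    least one base (merely touching intervals stay separate); each merged
    region records which datasets contributed to it.  Output regions are
    disjoint and sorted by (chromosome, start).
    """
    if not datasets:
        raise PeaktoolsError("merge_union requires at least one dataset")
    n = len(datasets)
    tagged = [
        (iv.chrom, iv.start, iv.end, ds)
        for ds, dataset in enumerate(datasets)
        for iv in dataset
    ]
    tagged.sort(key=lambda rec: rec[:3])

    merged: List[Tuple[GenomicInterval, Tuple[bool, ...]]] = []
    cur = None  # [chrom, start, end, member set]
    for chrom, start, end, ds in tagged:
        if cur is not None and chrom == cur[0] and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(ds)
        else:
            if cur is not None:
                merged.append(_finish_region(cur, n))
            cur = [chrom, start, end, {ds}]
    if cur is not None:
        merged.append(_finish_region(cur, n))
    return merged


def _finish_region(cur, n: int) -> Tuple[GenomicInterval, Tuple[bool, ...]]:
    chrom, start, end, members = cur
    bits = tuple(i in members for i in range(n))
    return GenomicInterval(chrom, start, end), bits


def randomize_peaks(
    S: Sequence[GenomicInterval],
    cfg: RandomizationConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[GenomicInterval]:
    """Draw one random dataset matching S's peak lengths and chromosomal
    distribution: each interval keeps its chromosome and length and gets
    a start uniform on [0, chrom_length - length].  Placements may
    overlap each other (no self-avoidance)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    starts = _random_starts(S, cfg, rng)
    return [
        GenomicInterval(iv.chrom, s, s + len(iv), name=iv.name)
        for iv, s in zip(S, starts)
    ]


def _random_starts(S, cfg: RandomizationConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform start per interval on [0, chrom_length - length], vectorized."""
    highs = np.empty(len(S), dtype=np.int64)
    for k, iv in enumerate(S):
        chrom_len = cfg.sizes.get(iv.chrom)
        if chrom_len is None:
            raise PeaktoolsError(f"chromosome {iv.chrom!r} missing from sizes table")
        length = len(iv)
        if length > chrom_len:
            raise PeaktoolsError(
                f"interval of length {length} does not fit on {iv.chrom} "
                f"(length {chrom_len})"
            )
        highs[k] = chrom_len - length
    if not len(S):
        return highs
    return rng.integers(0, highs + 1)


def overlap_pvalue(
    S1: Sequence[GenomicInterval],
    S2: Sequence[GenomicInterval],
    cfg: RandomizationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[int, float]:
    """Monte-Carlo enrichment P-value for the overlap of S1 with S2.

    The observed statistic is the number of S1 intervals hitting S2.
    S1 is randomized ``cfg.iterations`` times (S2 held fixed) and the
    add-one estimator ``p = (1 + #{n_i >= observed}) / (iterations + 1)``
    is returned, so p is never exactly 0 and always lies in (0, 1].
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    index = ContainmentIndex.build(S2)
    observed = _count_hits(S1, index)
    chroms = [iv.chrom for iv in S1]
    lengths = [len(iv) for iv in S1]
    exceed = 0
    for _ in range(cfg.iterations):
        starts = _random_starts(S1, cfg, rng)
        triples = zip(chroms, starts, starts + np.asarray(lengths))
        if _count_hits_raw(triples, index) >= observed:
            exceed += 1
    p = (1 + exceed) / (cfg.iterations + 1)
    return observed, p
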