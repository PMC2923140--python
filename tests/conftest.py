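"""Shared fixtures: seeded random interval / transcript generators."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from peaktools.core import GenomicInterval, Transcript

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000,
                     max_len=500, nested_fraction=0.3):
    """Random interval set with deliberate nesting and duplicate spans."""
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        if out and rng.random() < nested_fraction:
            host = out[int(rng.integers(0, len(out)))]
            if len(host) > 2:
                start = host.start + int(rng.integers(0, len(host) - 1))
                end = start + 1 + int(rng.integers(0, host.end - start))
                end = min(end, host.end)
                out.append(GenomicInterval(host.chrom, start, end, name=f"iv{i}"))
                continue
        start = int(rng.integers(0, max_pos))
        length = 1 + int(rng.integers(0, max_len))
        out.append(GenomicInterval(chrom, start, start + length, name=f"iv{i}"))
    # sprinkle exact duplicates to exercise the tie convention
    for j in range(0, len(out), 17):
        src = out[j]
        out.append(GenomicInterval(src.chrom, src.start, src.end, name=f"dup{j}"))
    return out


def random_transcripts(rng, n, chroms=("chr1", "chr2"), span=200_000,
                       nested_fraction=0.25):
    """Random stranded gene models, including nested and overlapping ones."""
    out = []
    for i in range(n):
        strand = "+" if rng.random() < 0.5 else "-"
        if out and rng.random() < nested_fraction:
            host = out[int(rng.integers(0, len(out)))]
            room = host.tx_end - host.tx_start
            if room > 10:
                length = 2 + int(rng.integers(0, room - 4))
                start = host.tx_start + int(
                    rng.integers(0, room - length + 1)
                )
                out.append(_make_transcript(rng, i, host.chrom, strand, start, length))
                continue
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = 10 + int(rng.integers(0, 20_000))
        start = int(rng.integers(0, span - length))
        out.append(_make_transcript(rng, i, chrom, strand, start, length))
    return out


def _make_transcript(rng, i, chrom, strand, start, length):
    end = start + length
    n_exons = 1 + int(rng.integers(0, min(4, max(length // 4, 1))))
    cut_points = sorted(
        int(c) for c in rng.choice(
            np.arange(start + 1, end), size=min(2 * n_exons - 2, length - 1),
            replace=False,
        )
    )
    bounds = [start] + cut_points + [end]
    exons = tuple(
        (bounds[k], bounds[k + 1]) for k in range(0, len(bounds) - 1, 2)
    )
    cds_start = cds_end = None
    if rng.random() < 0.7 and length >= 3:
        cds_start = start + int(rng.integers(0, length // 2))
        cds_end = cds_start + 1 + int(rng.integers(0, end - cds_start - 1))
    return Transcript(
        f"G{i}", f"T{i:05d}", chrom, strand, start, end, exons, cds_start, cds_end
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
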