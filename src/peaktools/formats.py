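"""Readers and writers for the file formats the toolkit touches.

Every parser normalizes to the internal 0-based half-open convention:

====================  =======================  =========================
format                on disk                  conversion applied
====================  =======================  =========================
BED / bedGraph        0-based half-open        none
GTF                   1-based inclusive        start - 1, end unchanged
WIG fixed/variable    1-based positions        position - 1
====================  =======================  =========================
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, List, Optional, Tuple, Union

from .core import (
    FORWARD,
    REVERSE,
    UNSTRANDED,
    GenomicInterval,
    ParseError,
    SignalProfile,
    Transcript,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_SKIP_PREFIXES = ("track", "browser", "#")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: PathLike) -> List[GenomicInterval]:
    """Parse a BED3-BED6 file into intervals, preserving input order.

    Column 4 becomes ``name``, 5 ``score`` (parsed as float, not
    range-checked), 6 ``strand``.  A literal ``.`` in the name or score
    column is treated as absent.  track/browser/comment lines are skipped.
    """
    intervals: List[GenomicInterval] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"expected >=3 tab-separated columns, got {len(fields)}", lineno
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {fields[1]!r}, {fields[2]!r}", lineno
                ) from None
            name = None
            if len(fields) > 3 and fields[3] != ".":
                name = fields[3]
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(f"non-numeric score {fields[4]!r}", lineno) from None
            strand = UNSTRANDED
            if len(fields) > 5 and fields[5] != ".":
                strand = fields[5]
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand, name, score)
                )
            except ValidationError as exc:
                raise ParseError(str(exc), lineno) from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    """Write intervals as BED, emitting only the columns each record needs.

    Round-trips through :func:`read_bed`: absent name/score/strand are
    written as ``.`` placeholders only when a later column is present.
    """
    with open(path, "w") as handle:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            n_cols = 3
            if iv.name is not None:
                n_cols = 4
            if iv.score is not None:
                n_cols = 5
            if iv.strand != UNSTRANDED:
                n_cols = 6
            if n_cols > 3:
                fields.append(iv.name if iv.name is not None else ".")
            if n_cols > 4:
                fields.append(_format_score(iv.score) if iv.score is not None else ".")
            if n_cols > 5:
                fields.append(iv.strand)
            handle.write("\t".join(fields) + "\n")


def _format_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(score)


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(raw: str, lineno: int) -> dict:
    attrs = dict(_ATTR_RE.findall(raw))
    if not attrs:
        raise ParseError(f"unparseable GTF attribute column {raw!r}", lineno)
    return attrs


def read_gtf(path: PathLike) -> List[Transcript]:
    """Parse GTF exon/CDS/transcript lines into :class:`Transcript` models.

    GTF coordinates (1-based inclusive) become 0-based half-open via
    ``(start - 1, end)``.  Exons are grouped per ``transcript_id`` and
    sorted; the transcript span is the hull of its exons unless an
    explicit ``transcript`` feature line is present; the CDS span is the
    hull of CDS lines.  Transcripts are returned in order of first
    appearance.
    """
    exons: dict = {}
    cds: dict = {}
    tx_span: dict = {}
    meta: dict = {}
    order: List[str] = []

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated columns, got {len(fields)}", lineno
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            feature = feature.lower()
            if feature not in ("exon", "cds", "transcript"):
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {start_s!r}, {end_s!r}", lineno
                ) from None
            if start < 0 or end <= start:
                raise ParseError(f"invalid feature span {start_s}-{end_s}", lineno)
            attrs = _parse_attributes(attr_s, lineno)
            tid = attrs.get("transcript_id")
            if not tid:
                raise ParseError(f"{feature} feature lacks transcript_id", lineno)
            if strand not in (FORWARD, REVERSE):
                raise ParseError(
                    f"transcript {tid}: strand {strand!r} rejected "
                    "(strand is required for downstream-gene and TSS queries)",
                    lineno,
                )
            gid = attrs.get("gene_id", tid)
            if tid not in meta:
                meta[tid] = (gid, chrom, strand)
                order.append(tid)
            elif meta[tid][1:] != (chrom, strand):
                raise ParseError(
                    f"transcript {tid}: inconsistent chromosome/strand", lineno
                )
            if feature == "exon":
                exons.setdefault(tid, []).append((start, end))
            elif feature == "cds":
                cds.setdefault(tid, []).append((start, end))
            else:
                tx_span[tid] = (start, end)

    transcripts: List[Transcript] = []
    for tid in order:
        gid, chrom, strand = meta[tid]
        ex = sorted(exons.get(tid, []))
        if not ex:
            if tid in tx_span:
                ex = [tx_span[tid]]
            else:
                raise ParseError(f"transcript {tid} has no exon features")
        if tid in tx_span:
            start, end = tx_span[tid]
        else:
            start, end = ex[0][0], max(e for _, e in ex)
        cds_start = cds_end = None
        if tid in cds:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        try:
            transcripts.append(
                Transcript(gid, tid, chrom, strand, start, end, tuple(ex),
                           cds_start, cds_end)
            )
        except ValidationError as exc:
            raise ParseError(str(exc)) from None
    return transcripts


def write_gtf(transcripts: Iterable[Transcript], path: PathLike,
              source: str = "peaktools") -> None:
    """Write transcripts as GTF 2.2 (converting back to 1-based inclusive)."""
    with open(path, "w") as handle:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'

            def line(feature: str, start: int, end: int) -> str:
                return "\t".join(
                    (t.chrom, source, feature, str(start + 1), str(end), ".",
                     t.strand, ".", attrs)
                ) + "\n"

            handle.write(line("transcript", t.tx_start, t.tx_end))
            for start, end in t.exons:
                handle.write(line("exon", start, end))
            if t.has_cds:
                handle.write(line("CDS", t.cds_start, t.cds_end))


# ---------------------------------------------------------------------------
# WIG (fixedStep / variableStep / bedGraph)
# ---------------------------------------------------------------------------

_KNOWN_DIRECTIVES = ("fixedStep", "variableStep")


def _parse_directive(line: str, lineno: int) -> dict:
    parts = line.split()
    out = {"_kind": parts[0]}
    for part in parts[1:]:
        if "=" not in part:
            raise ParseError(f"malformed {parts[0]} directive field {part!r}", lineno)
        key, value = part.split("=", 1)
        out[key] = value
    return out


def read_wig(path: PathLike) -> SignalProfile:
    """Parse a WIG file mixing fixedStep, variableStep and bedGraph records.

    WIG 1-based positions are shifted to 0-based; ``span``/``step`` are
    expanded to per-base depths.  A later value at an already-covered
    base overwrites the earlier one with a logged warning.
    """
    profile = SignalProfile()
    mode: Optional[str] = None
    chrom = ""
    pos = 0
    step = 1
    span = 1
    clashes = 0

    def deposit(c: str, p: int, depth: float, width: int, lineno: int) -> None:
        nonlocal clashes
        if depth < 0:
            raise ParseError(f"negative depth {depth}", lineno)
        if p < 0:
            raise ParseError(f"position underflow (WIG positions are 1-based)", lineno)
        for offset in range(width):
            if profile.set_depth(c, p + offset, depth):
                clashes += 1

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            first = line.split(None, 1)[0]
            if first in _KNOWN_DIRECTIVES:
                d = _parse_directive(line, lineno)
                if "chrom" not in d:
                    raise ParseError(f"{first} directive lacks chrom=", lineno)
                chrom = d["chrom"]
                span = int(d.get("span", 1))
                if span < 1:
                    raise ParseError(f"span must be >= 1, got {span}", lineno)
                if first == "fixedStep":
                    if "start" not in d:
                        raise ParseError("fixedStep directive lacks start=", lineno)
                    pos = int(d["start"]) - 1
                    step = int(d.get("step", 1))
                    mode = "fixed"
                else:
                    mode = "variable"
                continue

            fields = line.split()
            if len(fields) == 4:
                # bedGraph record (0-based half-open), allowed in any mode
                c, start_s, end_s, value_s = fields
                try:
                    start, end, value = int(start_s), int(end_s), float(value_s)
                except ValueError:
                    raise ParseError(f"malformed bedGraph record {line!r}", lineno) from None
                if end <= start:
                    raise ParseError(f"bedGraph span {start}-{end} is empty", lineno)
                deposit(c, start, value, end - start, lineno)
            elif len(fields) == 2:
                if mode != "variable":
                    raise ParseError(
                        "two-column record outside a variableStep block", lineno
                    )
                try:
                    p, value = int(fields[0]), float(fields[1])
                except ValueError:
                    raise ParseError(f"malformed variableStep record {line!r}", lineno) from None
                deposit(chrom, p - 1, value, span, lineno)
            elif len(fields) == 1:
                if mode != "fixed":
                    raise ParseError(
                        "one-column record outside a fixedStep block", lineno
                    )
                try:
                    value = float(fields[0])
                except ValueError:
                    raise ParseError(f"malformed fixedStep value {line!r}", lineno) from None
                deposit(chrom, pos, value, span, lineno)
                pos += step
            else:
                raise ParseError(f"unrecognized record {line!r}", lineno)

    if clashes:
        logger.warning(
            "%s: %d base(s) covered more than once; later values kept", path, clashes
        )
    return profile


def write_wig(profile: SignalProfile, path: PathLike) -> None:
    """Write a profile as fixedStep step=1 blocks over contiguous runs."""
    with open(path, "w") as handle:
        for chrom in profile.chromosomes():
            positions = profile.positions(chrom)
            block_start = None
            prev = None
            values: List[float] = []

            def flush() -> None:
                if block_start is None:
                    return
                handle.write(f"fixedStep chrom={chrom} start={block_start + 1} step=1\n")
                for v in values:
                    handle.write(f"{_format_score(v)}\n")

            for p in positions:
                if prev is None or p != prev + 1:
                    flush()
                    block_start = p
                    values = []
                values.append(profile.depth_at(chrom, p))
                prev = p
            flush()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_sequence(fasta, interval: GenomicInterval) -> str:
    """Fetch the genomic sequence of an interval from an indexed FASTA.

    ``fasta`` is a path or an open :class:`pyfaidx.Fasta`.  Reverse-strand
    intervals return the reverse complement.
    """
    import pyfaidx

    if not isinstance(fasta, pyfaidx.Fasta):
        fasta = pyfaidx.Fasta(str(fasta))
    if interval.chrom not in fasta:
        raise KeyError(f"chromosome {interval.chrom!r} not present in FASTA")
    record = fasta[interval.chrom]
    if interval.end > len(record):
        raise IndexError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {len(record)}"
        )
    seq = str(record[interval.start:interval.end])
    if interval.strand == REVERSE:
        seq = reverse_complement(seq)
    return seq


def write_fasta(records: Iterable[Tuple[str, str]], path: PathLike,
                width: int = 60) -> None:
    """Write (header, sequence) pairs as FASTA with wrapped lines."""
    with open(path, "w") as handle:
        for header, seq in records:
            handle.write(f">{header}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# chrom.sizes
# ---------------------------------------------------------------------------

def load_chrom_sizes(path: PathLike) -> dict:
    """Parse a two-column ``name<TAB>length`` chromosome-sizes table."""
    sizes: dict = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError("expected two columns: name, length", lineno)
            try:
                length = int(fields[1])
            except ValueError:
                raise ParseError(f"non-integer length {fields[1]!r}", lineno) from None
            if length <= 0:
                raise ParseError(f"non-positive chromosome length {length}", lineno)
            sizes[fields[0]] = length
    return sizes


def write_chrom_sizes(sizes: dict, path: PathLike) -> None:
    with open(path, "w") as handle:
        for chrom in sorted(sizes):
            handle.write(f"{chrom}\t{sizes[chrom]}\n")
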