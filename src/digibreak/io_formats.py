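"""Readers and writers for the pipeline's external formats.

All genomic coordinates inside the package are 0-based half-open
(BED-native). SAM's 1-based coordinates are converted at the parser
boundary and never leak further in. 1-based values appear only in
human-readable reports.

A *breakend* is one of the two single-nucleotide ends created by a
double-strand break; because library preparation is PCR-free, one
retained sequencing read corresponds to exactly one labelled break end,
so breakends are the package's unit of measurement.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pysam

__all__ = [
    "AlignedRead",
    "FlowcellCoord",
    "GenomicInterval",
    "BreakEnd",
    "read_fasta",
    "parse_illumina_read_name",
    "read_alignments",
    "write_breakends",
    "read_breakends",
    "read_bed_intervals",
    "write_bed_intervals",
]


class FormatError(ValueError):
    """Raised for malformed input files or records."""


@dataclass(frozen=True, order=True)
class FlowcellCoord:
    """Physical cluster position on an Illumina flow cell.

    Optical duplicates are neighbouring clusters on the same lane and
    tile, so these four fields are the key for optical deduplication.
    """

    lane: int
    tile: int
    x: int
    y: int

    def __post_init__(self) -> None:
        if min(self.lane, self.tile, self.x, self.y) < 0:
            raise ValueError("flow-cell coordinates must be non-negative")


@dataclass(frozen=True)
class AlignedRead:
    """One aligned sequencing read (the carrier for SAM/BAM records)."""

    read_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    mapq: int
    has_softclip: bool
    cigar: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"mapq out of range: {self.mapq}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval (BED record).

    Strand '.' is allowed for strand-blind intervals such as blacklist
    regions; breakends always carry a definite strand.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class BreakEnd:
    """A sequencing read reduced to its single-nucleotide break position."""

    chrom: str
    pos: int  # 0-based
    strand: str  # '+' or '-'
    sample_id: str = ""
    read_id: str = "."
    flowcell: FlowcellCoord | None = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("breakend position must be non-negative")
        if self.strand not in ("+", "-"):
            raise ValueError("breakend strand must be '+' or '-'")

    @property
    def key(self) -> tuple[str, int, str]:
        """Genomic identity (chrom, pos, strand) ignoring provenance."""
        return (self.chrom, self.pos, self.strand)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into {name: uppercase sequence}.

    Record order is preserved (dict insertion order). IUPAC ambiguity
    letters are kept as-is, only case-folded. Duplicate record names are
    a fatal ambiguity.
    """
    path = Path(path)
    genome: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks).upper()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name in genome:
                    raise FormatError(f"{path}:{lineno}: duplicate record {name!r}")
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence before first FASTA header"
                    )
                chunks.append(line)
    if name is None:
        raise FormatError(f"{path}: empty or headerless FASTA")
    genome[name] = "".join(chunks).upper()
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Illumina read names

_ILLUMINA_MIN_FIELDS = 7


def parse_illumina_read_name(name: str) -> FlowcellCoord:
    """Extract (lane, tile, x, y) from a colon-delimited Illumina read name.

    Expects ``instrument:run:flowcell:lane:tile:x:y`` with optional
    trailing fields (a space-separated comment is ignored). Raises
    :class:`FormatError` for anything else; callers may treat that as
    "no flow-cell information", which exempts the read from optical
    deduplication.
    """
    head = name.split()[0] if name.strip() else ""
    fields = head.split(":")
    if len(fields) < _ILLUMINA_MIN_FIELDS:
        raise FormatError(
            f"read name {name!r} has {len(fields)} colon fields, need ≥7"
        )
    try:
        lane, tile, x, y = (int(f) for f in fields[3:7])
    except ValueError as exc:
        raise FormatError(f"non-integer positional field in {name!r}") from exc
    return FlowcellCoord(lane=lane, tile=tile, x=x, y=y)


# ---------------------------------------------------------------------------
# SAM/BAM


def read_alignments(path: str | Path) -> Iterator[AlignedRead]:
    """Stream mapped reads from a SAM/BAM file as :class:`AlignedRead`.

    Unmapped and secondary/supplementary records are skipped. SAM's
    1-based coordinates are converted to 0-based half-open here.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cigar = rec.cigarstring or ""
            yield AlignedRead(
                read_id=rec.query_name or ".",
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
                has_softclip="S" in cigar,
                cigar=cigar,
            )


# ---------------------------------------------------------------------------
# BED


def write_breakends(breakends: Iterable[BreakEnd], path: str | Path) -> None:
    """Write breakends as BED6 width-1 intervals (end = pos + 1)."""
    with open(path, "w") as fh:
        for be in breakends:
            fh.write(
                f"{be.chrom}\t{be.pos}\t{be.pos + 1}\t{be.read_id}\t.\t{be.strand}\n"
            )


def read_breakends(path: str | Path, sample_id: str = "") -> list[BreakEnd]:
    """Read a breakend BED6 file written by :func:`write_breakends`.

    Width must be exactly 1. If the read-id column is a parseable
    Illumina name the flow-cell coordinates are restored, so optical
    deduplication remains possible after a BED round-trip.
    """
    out: list[BreakEnd] = []
    for lineno, fields in _bed_rows(path, min_cols=6):
        chrom, start, end, name, _score, strand = fields[:6]
        start_i, end_i = _bed_coords(path, lineno, start, end)
        if end_i != start_i + 1:
            raise FormatError(
                f"{path}:{lineno}: breakend interval must have width 1, "
                f"got [{start_i}, {end_i})"
            )
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: breakend strand {strand!r}")
        try:
            fc = parse_illumina_read_name(name)
        except FormatError:
            fc = None
        out.append(
            BreakEnd(
                chrom=chrom,
                pos=start_i,
                strand=strand,
                sample_id=sample_id,
                read_id=name,
                flowcell=fc,
            )
        )
    return out


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (blacklists, site lists)."""
    out: list[GenomicInterval] = []
    for lineno, fields in _bed_rows(path, min_cols=3):
        chrom, start, end = fields[:3]
        start_i, end_i = _bed_coords(path, lineno, start, end)
        if end_i <= start_i:
            raise FormatError(f"{path}:{lineno}: empty interval")
        strand = fields[5] if len(fields) >= 6 else "."
        if strand not in ("+", "-", "."):
            raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
        out.append(GenomicInterval(chrom=chrom, start=start_i, end=end_i, strand=strand))
    return out


def write_bed_intervals(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Iterable[str] | None = None,
    scores: Iterable[object] | None = None,
) -> None:
    names = list(names) if names is not None else None
    scores = list(scores) if scores is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            score = scores[i] if scores else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def _bed_rows(path: str | Path, min_cols: int):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected ≥{min_cols} columns, got {len(fields)}"
                )
            yield lineno, fields


def _bed_coords(path, lineno, start: str, end: str) -> tuple[int, int]:
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start_i < 0:
        raise FormatError(f"{path}:{lineno}: negative coordinate")
    return start_i, end_i
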