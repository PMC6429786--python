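"""Streaming FASTA/FASTQ reading and writing, plain or gzip.

Readers yield one :class:`SequenceRecord` at a time so memory use is
independent of file size.  Format is auto-detected from the first
non-blank character ('>' FASTA, '@' FASTQ) and gzip from the magic bytes.
Record parsing is delegated to Biopython's lightweight tuple iterators.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import ScoreRecord

__all__ = [
    "SequenceRecord",
    "ParseError",
    "open_reads",
    "sniff_format",
    "write_reads",
    "write_scores",
]

GZIP_MAGIC = b"\x1f\x8b"


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ input, naming the offending record."""


@dataclass(frozen=True)
class SequenceRecord:
    """One read: id (first whitespace-delimited token), optional trailing
    description, sequence, and quality string (FASTQ only)."""

    read_id: str
    sequence: str
    description: str = ""
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParseError(
                f"record {self.read_id!r}: quality length "
                f"{len(self.quality)} != sequence length {len(self.sequence)}"
            )

    @property
    def header(self) -> str:
        """Id and description re-joined as written in the file header."""
        return f"{self.read_id} {self.description}" if self.description else self.read_id


def _split_title(title: str) -> tuple[str, str]:
    parts = title.split(None, 1)
    if not parts:
        return "", ""
    return parts[0], parts[1] if len(parts) > 1 else ""


def _open_text(path: str | Path) -> IO[str]:
    """Open plain or gzip text transparently (gzip sniffed by magic bytes)."""
    with open(path, "rb") as raw:
        magic = raw.read(2)
    if magic == GZIP_MAGIC:
        return gzip.open(path, "rt")
    return open(path, "r")


def sniff_format(path: str | Path) -> str:
    """Return 'fasta' or 'fastq' from the first non-blank character."""
    with _open_text(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            first = line[0]
            if first == ">":
                return "fasta"
            if first == "@":
                return "fastq"
            raise ParseError(
                f"{path}: unrecognized leading character {first!r} "
                "(expected '>' for FASTA or '@' for FASTQ)"
            )
    raise ParseError(f"{path}: empty file, cannot detect format")


def open_reads(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA or FASTQ file, optionally gzipped.

    Yields records in file order.  Malformed records (quality/sequence
    length mismatch, truncated FASTQ) raise :class:`ParseError` naming the
    record.
    """
    fmt = sniff_format(path)
    with _open_text(path) as handle:
        if fmt == "fasta":
            for title, seq in SimpleFastaParser(handle):
                read_id, desc = _split_title(title)
                yield SequenceRecord(read_id, seq, desc)
        else:
            try:
                for title, seq, qual in FastqGeneralIterator(handle):
                    read_id, desc = _split_title(title)
                    if len(qual) != len(seq):
                        raise ParseError(
                            f"record {read_id!r}: quality length "
                            f"{len(qual)} != sequence length {len(seq)}"
                        )
                    yield SequenceRecord(read_id, seq, desc, qual)
            except ValueError as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(f"{path}: {exc}") from exc


def _open_write(path: str | Path) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def write_reads(
    records: Iterable[SequenceRecord],
    path: str | Path,
    fmt: str,
) -> int:
    """Write records as FASTA or FASTQ ('.gz' suffix gzips); returns count.

    FASTA output is unwrapped (one sequence line per record).  Writing a
    record without quality as FASTQ raises ``ValueError``.
    """
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"format must be 'fasta' or 'fastq', got {fmt!r}")
    n = 0
    with _open_write(path) as out:
        for rec in records:
            if fmt == "fasta":
                out.write(f">{rec.header}\n{rec.sequence}\n")
            else:
                if rec.quality is None:
                    raise ValueError(
                        f"record {rec.read_id!r} has no quality; "
                        "cannot write FASTQ"
                    )
                out.write(f"@{rec.header}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n


SCORE_HEADER = "read_id\tlength\tunique_kmers\tscore"


def write_scores(scores: Iterable[ScoreRecord], path: str | Path) -> int:
    """Write a per-read score table as headered TSV; returns rows written.

    Columns: read_id, length, unique_kmers, score (4 decimal places,
    round-half-even).
    """
    n = 0
    with _open_write(path) as out:
        out.write(SCORE_HEADER + "\n")
        for rec in scores:
            out.write(
                f"{rec.read_id}\t{rec.length}\t{rec.unique_kmers}"
                f"\t{rec.score:.4f}\n"
            )
            n += 1
    return n
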