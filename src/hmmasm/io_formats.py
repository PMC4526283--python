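"""Sequence and alignment I/O plus read preprocessing.

Reads stream through lightweight :class:`SequenceRecord` objects so that
graph building never holds a whole metagenome in memory at once.  FASTA and
FASTQ are parsed by small streaming readers that report the offending line
number on malformed input; Stockholm alignments are delegated to
``Bio.AlignIO``.  Gzip-compressed files are handled transparently by suffix.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from Bio import AlignIO

GAP_CHARS = frozenset("-.")

#: Phred floor matching both Illumina "B" (Phred+64) and "#" (Phred+33) trims.
DEFAULT_QUALITY_FLOOR = 2


class FormatError(ValueError):
    """An input file violates its declared format."""


@dataclass
class SequenceRecord:
    """A single nucleotide or amino-acid sequence, optionally with quality.

    ``quality`` holds per-residue integer Phred scores and, when present,
    must be the same length as ``residues``.
    """

    id: str
    description: str = ""
    residues: str = ""
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.residues):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MultipleAlignment:
    """A set of equal-length gapped sequences."""

    records: list[SequenceRecord]
    n_columns: int = field(default=-1)

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment contains no sequences")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            shortest = min(self.records, key=lambda r: len(r.residues))
            raise FormatError(
                f"ragged alignment: record {shortest.id!r} has length "
                f"{len(shortest.residues)}, expected a uniform width"
            )
        width = lengths.pop()
        if self.n_columns == -1:
            self.n_columns = width
        elif self.n_columns != width:
            raise FormatError(
                f"declared column count {self.n_columns} != actual {width}"
            )


PathLike = Union[str, Path]


def _open(path: PathLike, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: PathLike) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA file in file order, preserving case."""
    with _open(path) as fh:
        header: Optional[str] = None
        header_line = 0
        chunks: list[str] = []
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if header is not None:
                    yield _flush_fasta(header, header_line, chunks)
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FormatError(
                        f"line {lineno}: sequence data before first '>' header"
                    )
                chunks.append(line.strip())
        if header is not None:
            yield _flush_fasta(header, header_line, chunks)


def _flush_fasta(header: str, header_line: int, chunks: list[str]) -> SequenceRecord:
    residues = "".join(chunks)
    if not residues:
        raise FormatError(f"line {header_line}: record {header.split()[0]!r} has an empty sequence")
    parts = header.split(None, 1)
    return SequenceRecord(
        id=parts[0],
        description=parts[1] if len(parts) > 1 else "",
        residues=residues,
    )


_PHRED_OFFSETS = {"phred33": 33, "phred64": 64}


def read_fastq(path: PathLike, encoding: str = "phred33") -> Iterator[SequenceRecord]:
    """Stream 4-line FASTQ records; ``encoding`` selects Phred+33 or Phred+64."""
    try:
        offset = _PHRED_OFFSETS[encoding]
    except KeyError:
        raise ValueError(f"unknown FASTQ quality encoding {encoding!r}") from None
    with _open(path) as fh:
        lineno = 0
        while True:
            head = fh.readline()
            if not head:
                return
            lineno += 1
            head = head.rstrip("\r\n")
            if not head.strip():
                continue
            if not head.startswith("@"):
                raise FormatError(f"line {lineno}: expected '@' record header, got {head[:20]!r}")
            seq = fh.readline().rstrip("\r\n")
            plus = fh.readline().rstrip("\r\n")
            qual = fh.readline().rstrip("\r\n")
            if not qual and not plus:
                raise FormatError(f"line {lineno}: truncated FASTQ record {head[1:].split()[0]!r}")
            lineno += 3
            if not plus.startswith("+"):
                raise FormatError(f"line {lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise FormatError(
                    f"line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            parts = head[1:].split(None, 1)
            yield SequenceRecord(
                id=parts[0],
                description=parts[1] if len(parts) > 1 else "",
                residues=seq,
                quality=[ord(c) - offset for c in qual],
            )


def quality_trim(
    record: SequenceRecord, floor: int = DEFAULT_QUALITY_FLOOR
) -> SequenceRecord:
    """Remove the maximal trailing run of bases with quality <= ``floor``.

    Matches the Illumina end-trim convention ("B" in Phred+64 data, "#" in
    Phred+33 data, both Phred 2).  Idempotent; may return an empty record,
    which callers should discard.
    """
    if record.quality is None:
        raise ValueError(f"record {record.id!r} has no quality scores")
    end = len(record.quality)
    while end > 0 and record.quality[end - 1] <= floor:
        end -= 1
    if end == len(record.quality):
        return record
    return replace(record, residues=record.residues[:end], quality=record.quality[:end])


def read_alignment(path: PathLike, dialect: Optional[str] = None) -> MultipleAlignment:
    """Read an aligned FASTA or Stockholm alignment.

    ``dialect`` is ``"fasta"`` or ``"stockholm"``; when omitted the format is
    sniffed from the first line.  Case of residues is preserved; Stockholm
    annotation (``#=GC`` etc.) lines are ignored.
    """
    if dialect is None:
        with _open(path) as fh:
            first = fh.readline()
        dialect = "stockholm" if first.startswith("# STOCKHOLM") else "fasta"
    if dialect == "fasta":
        records = list(read_fasta(path))
        return MultipleAlignment(records)
    if dialect == "stockholm":
        with _open(path) as fh:
            aln = AlignIO.read(fh, "stockholm")
        records = [
            SequenceRecord(id=rec.id, description=rec.description or "", residues=str(rec.seq))
            for rec in aln
        ]
        return MultipleAlignment(records)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_fasta(
    records: Iterable[SequenceRecord], path: PathLike, wrap: int = 60
) -> None:
    """Write records as FASTA; ``wrap <= 0`` writes one line per sequence."""
    with _open(path, "wt") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            if wrap and wrap > 0:
                for i in range(0, len(rec.residues), wrap):
                    fh.write(rec.residues[i : i + wrap] + "\n")
            else:
                fh.write(rec.residues + "\n")


def write_fastq(
    records: Iterable[SequenceRecord], path: PathLike, encoding: str = "phred33"
) -> None:
    offset = _PHRED_OFFSETS[encoding]
    with _open(path, "wt") as fh:
        for rec in records:
            if rec.quality is None:
                raise ValueError(f"record {rec.id!r} has no quality scores")
            qual = "".join(chr(q + offset) for q in rec.quality)
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n{qual}\n")
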