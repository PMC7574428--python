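"""FASTA/FASTQ reading and writing, plain or gzip, with line-accurate errors.

Sequences are folded to upper case on ingest; FASTQ plus-lines and quality
strings are preserved verbatim so filtered records round-trip byte-identically
(modulo the case folding).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator


@dataclass
class SeqRecord:
    """One sequence record; ``qual``/``plus`` are None for FASTA input."""

    id: str
    seq: str
    qual: str | None = None
    plus: str = "+"
    desc: str = ""

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def header(self) -> str:
        return f"{self.id} {self.desc}".rstrip()


class SequenceParseError(ValueError):
    pass


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff(handle: io.TextIOBase) -> str:
    for line in handle:
        if line.strip():
            if line[0] == ">":
                return "fasta"
            if line[0] == "@":
                return "fastq"
            raise SequenceParseError(
                f"line 1: cannot determine format from leading {line[0]!r}"
            )
    raise SequenceParseError("empty sequence file")


def read_sequences(path) -> Iterator[SeqRecord]:
    """Stream records from a FASTA or FASTQ file (gzip transparent)."""
    with _open_text(path) as probe:
        fmt = _sniff(probe)
    with _open_text(path) as fh:
        if fmt == "fasta":
            yield from _iter_fasta(fh)
        else:
            yield from _iter_fastq(fh)


def _iter_fasta(fh) -> Iterator[SeqRecord]:
    header: str | None = None
    chunks: list[str] = []
    lineno = 0
    for lineno, line in enumerate(fh, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line[0] == ">":
            if header is not None:
                yield _fasta_record(header, chunks)
            header = line[1:]
            chunks = []
        else:
            if header is None:
                raise SequenceParseError(f"line {lineno}: sequence before first '>' header")
            chunks.append(line)
    if header is not None:
        yield _fasta_record(header, chunks)


def _fasta_record(header: str, chunks: list[str]) -> SeqRecord:
    name, _, desc = header.partition(" ")
    return SeqRecord(id=name, seq="".join(chunks).upper(), desc=desc)


def _iter_fastq(fh) -> Iterator[SeqRecord]:
    lineno = 0
    while True:
        lines = []
        for _ in range(4):
            line = fh.readline()
            if line == "":
                break
            lineno += 1
            lines.append(line.rstrip("\n"))
        if not lines or (len(lines) == 1 and not lines[0]):
            return
        if len(lines) < 4:
            raise SequenceParseError(
                f"line {lineno}: truncated FASTQ record ({len(lines)} of 4 lines)"
            )
        head, seq, plus, qual = lines
        if not head.startswith("@"):
            raise SequenceParseError(f"line {lineno - 3}: expected '@', got {head[:1]!r}")
        if not plus.startswith("+"):
            raise SequenceParseError(f"line {lineno - 1}: expected '+', got {plus[:1]!r}")
        if len(seq) != len(qual):
            raise SequenceParseError(
                f"line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        name, _, desc = head[1:].partition(" ")
        yield SeqRecord(id=name, seq=seq.upper(), qual=qual, plus=plus, desc=desc)


def write_fasta(records: Iterable[SeqRecord], path, wrap: int = 80) -> int:
    """Write records as FASTA, wrapping sequence at ``wrap`` columns."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.header}\n")
            seq = rec.seq
            if wrap and wrap > 0:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")
            else:
                fh.write(seq + "\n")
            n += 1
    return n


def write_fastq(records: Iterable[SeqRecord], path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            fh.write(f"@{rec.header}\n{rec.seq}\n{rec.plus}\n{qual}\n")
            n += 1
    return n
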