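"""Streaming FASTA/FASTQ reading and FASTA writing.

Input files may be plain or gzip-compressed (detected from the magic
bytes); format is auto-detected from the first record character ('>'
FASTA, '@' FASTQ).  Parsing is strict and streaming: malformed records
raise :class:`SequenceParseError` carrying the offending line number.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

__all__ = ["ReadRecord", "SequenceParseError", "read_sequences", "write_unitigs", "write_fasta", "write_fastq"]

_WRAP = 80


class SequenceParseError(ValueError):
    """A malformed FASTA/FASTQ record, with its line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


@dataclass
class ReadRecord:
    """One sequencing read: id, sequence (may contain N), optional quality."""

    id: str
    sequence: str
    quality: str | None = None


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(source):
    """Iterate :class:`ReadRecord` from a FASTA/FASTQ path or text stream.

    Streaming (constant memory in file size); record ids are the header
    token before the first whitespace.
    """
    if isinstance(source, (str, Path)):
        handle = _open_text(source)
        own = True
    else:
        handle = source
        own = False
    try:
        first = handle.readline()
        lineno = 1
        while first and not first.strip():
            first = handle.readline()
            lineno += 1
        if not first:
            return
        if first.startswith(">"):
            yield from _parse_fasta(handle, first, lineno)
        elif first.startswith("@"):
            yield from _parse_fastq(handle, first, lineno)
        else:
            raise SequenceParseError(
                lineno, f"unrecognised format: first record starts with {first[0]!r}"
            )
    finally:
        if own:
            handle.close()


def _parse_fasta(handle, first, lineno):
    header = first
    header_line = lineno
    chunks = []
    for line in handle:
        lineno += 1
        if line.startswith(">"):
            yield _fasta_record(header, chunks, header_line)
            header, header_line, chunks = line, lineno, []
        else:
            chunks.append(line.strip())
    yield _fasta_record(header, chunks, header_line)


def _fasta_record(header, chunks, header_line):
    name = header[1:].split(None, 1)
    if not name:
        raise SequenceParseError(header_line, "empty FASTA header")
    return ReadRecord(name[0], "".join(chunks))


def _parse_fastq(handle, first, lineno):
    head = first
    while True:
        if not head.startswith("@"):
            raise SequenceParseError(
                lineno, f"expected '@' header, got {head.strip()[:30]!r}"
            )
        name = head[1:].split(None, 1)
        if not name:
            raise SequenceParseError(lineno, "empty FASTQ header")
        seq = handle.readline()
        if not seq:
            raise SequenceParseError(lineno + 1, "truncated record: missing sequence")
        plus = handle.readline()
        if not plus:
            raise SequenceParseError(lineno + 2, "truncated record: missing '+' line")
        if not plus.startswith("+"):
            raise SequenceParseError(
                lineno + 2, f"expected '+' separator, got {plus.strip()[:30]!r}"
            )
        qual = handle.readline()
        if not qual:
            raise SequenceParseError(lineno + 3, "truncated record: missing quality")
        seq = seq.strip()
        qual = qual.strip()
        if len(qual) != len(seq):
            raise SequenceParseError(
                lineno + 3,
                f"quality length {len(qual)} != sequence length {len(seq)}",
            )
        yield ReadRecord(name[0], seq, qual)
        lineno += 4
        head = handle.readline()
        while head and not head.strip():
            lineno += 1
            head = handle.readline()
        if not head:
            return


def _write_wrapped(fh, seq):
    for i in range(0, len(seq), _WRAP):
        fh.write(seq[i : i + _WRAP])
        fh.write("\n")


def write_unitigs(unitigs, path) -> None:
    """Write assembled unitigs as FASTA, 80 columns, deterministic order.

    Headers: ``>unitig_<id> len=<length> seed=<seed read id>``.
    """
    with open(path, "wt") as fh:
        for u in unitigs:
            fh.write(f">unitig_{u.id} len={u.length} seed={u.seed_id}\n")
            _write_wrapped(fh, u.sequence)


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs or ReadRecords as wrapped FASTA."""
    with open(path, "wt") as fh:
        for rec in records:
            rid, seq = (rec.id, rec.sequence) if isinstance(rec, ReadRecord) else rec
            fh.write(f">{rid}\n")
            _write_wrapped(fh, seq)


def write_fastq(records, path) -> None:
    """Write ReadRecords as FASTQ (constant quality if none present)."""
    with open(path, "wt") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
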