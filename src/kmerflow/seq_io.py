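"""FASTA/FASTQ readers, record chunking, and the count-table TSV format.

Parsing is delegated to Biopython's SeqIO; records come back as lightweight
(id, seq) pairs with the sequence uppercased (counting is case-insensitive,
so soft-masked bases are treated like their uppercase forms). FASTQ quality
strings are read and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

from Bio import SeqIO

from .errors import FormatError

if TYPE_CHECKING:  # pragma: no cover
    from .counting import CountTable


@dataclass(frozen=True)
class SequenceRecord:
    """One input sequence: a non-empty identifier and its (possibly empty,
    possibly ambiguous) base string."""

    id: str
    seq: str


def _parse(path, fmt: str) -> Iterator[SequenceRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as handle:
        if fmt == "fasta":
            # Bio.SeqIO silently yields nothing for a non-FASTA first line;
            # enforce the header contract ourselves.
            head = handle.readline()
            while head and not head.strip():
                head = handle.readline()
            if head and not head.startswith(">"):
                raise FormatError(f"{path}: first non-empty line is not a '>' header")
            handle.seek(0)
        try:
            for rec in SeqIO.parse(handle, fmt):
                yield SequenceRecord(id=rec.id, seq=str(rec.seq).upper())
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc


def read_fasta(path) -> Iterator[SequenceRecord]:
    """Iterate records of a (possibly multi-line) FASTA file, in file order."""
    return _parse(path, "fasta")


def read_fastq(path) -> Iterator[SequenceRecord]:
    """Iterate records of a 4-line-per-record FASTQ file; qualities dropped."""
    return _parse(path, "fastq")


def read_any(path) -> Iterator[SequenceRecord]:
    """Dispatch on file extension: .fq/.fastq as FASTQ, otherwise FASTA."""
    suffix = Path(path).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return read_fastq(path)
    return read_fasta(path)


def chunk_records(
    records: Iterable[SequenceRecord], target_chunk_bases: int
) -> Iterator[list[SequenceRecord]]:
    """Greedily group records into chunks of roughly target_chunk_bases.

    A record is never split; a chunk is emitted as soon as its total length
    reaches the target, so chunks approximate equal shares of work.
    """
    if target_chunk_bases < 1:
        raise ValueError("target_chunk_bases must be >= 1")
    chunk: list[SequenceRecord] = []
    size = 0
    for rec in records:
        chunk.append(rec)
        size += len(rec.seq)
        if size >= target_chunk_bases:
            yield chunk
            chunk, size = [], 0
    if chunk:
        yield chunk


def write_counts(table: "CountTable", path) -> None:
    """Write a count table as sorted TSV: one ``KMER<TAB>COUNT`` line per
    k-mer, ascending lexicographically (A<C<G<T) for reproducible output."""
    from .encoding import value_to_string

    with open(path, "w") as out:
        for key in sorted(table.counts):
            out.write(f"{value_to_string(key, table.k)}\t{table.counts[key]}\n")


def read_counts(path, mode: str = "canonical") -> "CountTable":
    """Read a TSV count file back into a CountTable (round-trip of
    write_counts)."""
    from .counting import CountTable
    from .encoding import pack_value

    counts: dict[int, int] = {}
    k = 0
    with open(path) as handle:
        for line in handle:
            if not line.strip():
                continue
            try:
                kmer, cnt = line.rstrip("\n").split("\t")
            except ValueError as exc:
                raise FormatError(f"{path}: bad count line {line!r}") from exc
            k = len(kmer)
            counts[pack_value(kmer)] = int(cnt)
    return CountTable(counts=counts, k=k, mode=mode)


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    """Write records as FASTA with fixed line width (shared fixture writer)."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    """Write records as 4-line FASTQ with placeholder qualities."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f"@{rec.id}\n{rec.seq}\n+\n{'I' * len(rec.seq)}\n")
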