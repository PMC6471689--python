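"""Stage 2: aggregate superkmers into k-mer counts, merge partitions.

Each partition's superkmers are expanded window-by-window into a hash table
keyed by the packed k-mer (canonicalized against the reverse complement in
canonical mode, the default strand convention). Because signature routing
sends every instance of a k-mer to exactly one partition, partition tables
have disjoint key sets; a key appearing twice at merge time signals a
routing bug, not data. Counts are plain (arbitrary-precision) integers —
metagenome-scale totals overflow 32 bits.

``naive_count`` is the redundant sliding-window baseline, kept as the
independent oracle the pipeline is verified against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .encoding import pack_value, value_to_string
from .errors import KmerflowError, ParameterError, PartitionViolationError
from .superkmer import Superkmer, clean_fragments

_RC_CODE = (3, 2, 1, 0)  # 2-bit complement: A<->T, C<->G


def _rc_value(v: int, k: int) -> int:
    """Reverse complement of a packed k-mer value, in packed form."""
    out = 0
    for _ in range(k):
        out = (out << 2) | _RC_CODE[v & 3]
        v >>= 2
    return out


@dataclass
class CountTable:
    """Occurrence counts keyed by packed k-mer value.

    In canonical mode every key equals its own canonical form (the smaller
    of k-mer and reverse complement); forward mode counts literal windows.
    """

    counts: dict[int, int]
    k: int
    mode: str = "canonical"

    def get(self, kmer: str) -> int:
        key = pack_value(kmer)
        if self.mode == "canonical":
            key = min(key, _rc_value(key, self.k))
        return self.counts.get(key, 0)

    def items_decoded(self):
        for key in sorted(self.counts):
            yield value_to_string(key, self.k), self.counts[key]


def count_partition(
    superkmers: Iterable[Superkmer], k: int, mode: str = "canonical"
) -> CountTable:
    """Count every constituent k-mer of every superkmer into a hash table."""
    if mode not in ("canonical", "forward"):
        raise ParameterError(f"unknown mode: {mode!r}")
    counts: dict[int, int] = {}
    mask = (1 << (2 * k)) - 1
    canonical = mode == "canonical"
    for sk in superkmers:
        if sk.k != k:
            raise KmerflowError(f"superkmer has k={sk.k}, table has k={k}")
        v = sk.packed.value()
        # slide a 2k-bit window from the leftmost k-mer to the rightmost
        for shift in range(2 * (sk.packed.length - k), -1, -2):
            key = (v >> shift) & mask
            if canonical:
                key = min(key, _rc_value(key, k))
            counts[key] = counts.get(key, 0) + 1
    return CountTable(counts=counts, k=k, mode=mode)


def merge_tables(tables: list[CountTable]) -> CountTable:
    """Union of per-partition tables; keys must be pairwise disjoint."""
    if not tables:
        raise ParameterError("nothing to merge")
    k, mode = tables[0].k, tables[0].mode
    merged: dict[int, int] = {}
    for table in tables:
        if table.k != k or table.mode != mode:
            raise KmerflowError("tables disagree on k or mode")
        for key, cnt in table.counts.items():
            if key in merged:
                raise PartitionViolationError(
                    f"k-mer {value_to_string(key, k)} present in two partitions"
                )
            merged[key] = cnt
    return CountTable(counts=merged, k=k, mode=mode)


def naive_count(records, k: int, mode: str = "canonical") -> CountTable:
    """Direct sliding-window counter over cleaned fragments (oracle).

    No superkmers, no partitioning: every window of every fragment is
    counted one at a time.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if mode not in ("canonical", "forward"):
        raise ParameterError(f"unknown mode: {mode!r}")
    counts: dict[int, int] = {}
    canonical = mode == "canonical"
    for rec in records:
        for frag in clean_fragments(rec.seq):
            for i in range(len(frag) - k + 1):
                key = pack_value(frag[i : i + k])
                if canonical:
                    key = min(key, _rc_value(key, k))
                counts[key] = counts.get(key, 0) + 1
    return CountTable(counts=counts, k=k, mode=mode)


def summarize(table: CountTable) -> dict[str, int]:
    """Distinct (unique species) and total (occurrences) k-mer counts."""
    return {"distinct": len(table.counts), "total": sum(table.counts.values())}
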