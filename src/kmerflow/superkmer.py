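"""Signature computation and superkmer extraction (stage 1 core).

A *signature* of a k-mer is its smallest canonical m-mer restricted to an
allowed set: m-mers that start with AAA or ACA, or contain AA anywhere past
their first position, are excluded. The filter flattens the frequency skew
of plain minimizers (low-lexicographic m-mers such as poly-A are extremely
common). Runs of consecutive k-mers sharing one signature are merged into a
*superkmer* — a variant of minimum substring partitioning — so a fragment of
n bases is carried by far fewer than n-k+1 overlapping windows while every
instance of a k-mer still lands in the partition of its signature.

If no allowed m-mer exists in a window (e.g. poly-A sequence) the smallest
canonical m-mer is used anyway, flagged ``allowed=False``; counting only
needs the choice to be deterministic.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass

from . import encoding
from .encoding import PackedSeq
from .errors import ParameterError

_NON_ACGT = re.compile(r"[^ACGT]+")


@dataclass(frozen=True)
class Signature:
    """An m-length canonical minimizer; the partition key of a superkmer."""

    mmer: str
    allowed: bool

    def value(self) -> int:
        return encoding.pack_value(self.mmer)


@dataclass(frozen=True)
class Superkmer:
    """A maximal run of consecutive k-mers sharing one signature, stored
    packed. Carries ``len - k + 1`` k-mers overlapping by k-1 symbols."""

    packed: PackedSeq
    k: int
    signature: Signature

    @property
    def n_kmers(self) -> int:
        return self.packed.length - self.k + 1


def is_allowed(mmer: str) -> bool:
    """Whether an m-mer may serve as a signature.

    Excluded: starts with AAA, starts with ACA, or contains AA anywhere
    other than at its very beginning.
    """
    if len(mmer) < 3:
        raise ParameterError("signature filter needs length >= 3")
    if mmer.startswith("AAA") or mmer.startswith("ACA"):
        return False
    return "AA" not in mmer[1:]


def _window_keys(fragment: str, m: int) -> list[tuple[bool, str]]:
    """Per-position sort keys (disallowed-flag, canonical m-mer) for every
    m-window of the fragment; min over a range yields the signature."""
    n = len(fragment)
    rc = encoding.reverse_complement(fragment)
    keys = []
    for i in range(n - m + 1):
        fwd = fragment[i : i + m]
        rev = rc[n - m - i : n - i]
        canon = fwd if fwd <= rev else rev
        keys.append((not is_allowed(canon), canon))
    return keys


def signature_of(kmer: str, m: int) -> Signature:
    """The signature of a single k-mer: the smallest allowed canonical m-mer
    among its k-m+1 windows, or the smallest canonical m-mer overall when
    none is allowed (fallback, flagged)."""
    if not 3 <= m <= len(kmer):
        raise ParameterError(f"need 3 <= m <= k, got m={m}, k={len(kmer)}")
    bad, canon = min(_window_keys(kmer, m))
    return Signature(mmer=canon, allowed=not bad)


def clean_fragments(seq: str) -> list[str]:
    """Uppercase and split a raw sequence at every non-ACGT character."""
    return [f for f in _NON_ACGT.split(seq.upper()) if f]


def split_superkmers(fragment: str, k: int, m: int) -> list[Superkmer]:
    """Break an ACGT fragment into superkmers.

    Scans k-mers left to right; a new superkmer starts exactly where the
    signature changes, and adjacent superkmers overlap by k-1 symbols so
    the constituent k-mer sequence is preserved. Fragments shorter than k
    yield an empty list.

    The per-window signature is a sliding minimum over the per-position
    keys of :func:`_window_keys`, maintained with a monotonic deque.
    """
    n = len(fragment)
    if n < k:
        return []
    if not 3 <= m <= k:
        raise ParameterError(f"need 3 <= m <= k, got m={m}, k={k}")

    keys = _window_keys(fragment, m)
    window = k - m + 1  # m-windows per k-mer

    out: list[Superkmer] = []
    start = 0  # fragment offset of the current superkmer
    current: tuple[bool, str] | None = None
    dq: deque[int] = deque()  # indices into keys, keys increasing

    def push(j: int) -> None:
        while dq and keys[dq[-1]] > keys[j]:
            dq.pop()
        dq.append(j)

    for j in range(window - 1):  # seed all but the last index of window 0
        push(j)
    for i in range(n - k + 1):  # i: k-mer start; m-windows i .. i+window-1
        push(i + window - 1)
        while dq[0] < i:
            dq.popleft()
        sig_key = keys[dq[0]]
        if current is None:
            current = sig_key
        elif sig_key != current:
            out.append(_make(fragment[start : i - 1 + k], k, current))
            start, current = i, sig_key
    out.append(_make(fragment[start:], k, current))
    return out


def _make(seq: str, k: int, key: tuple[bool, str]) -> Superkmer:
    return Superkmer(
        packed=encoding.pack(seq),
        k=k,
        signature=Signature(mmer=key[1], allowed=not key[0]),
    )
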