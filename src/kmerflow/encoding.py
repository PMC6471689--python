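"""2-bit packed DNA encoding over 64-bit words.

Each of A, C, G, T maps to a 2-bit code (A=0, C=1, G=2, T=3, preserving
lexicographic order), and a sequence is packed 31 symbols per 64-bit word:
2 bits x 31 = 62 bits of payload, with the most significant bit reserved
(always zero) so every word stays within the signed-64-bit range. The first
symbol of each word occupies the highest occupied bit pair, so comparing
words as integers agrees with comparing the underlying strings. The last
word is left-padded with zero bits and the symbol count is stored alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CorruptionError, InvalidSymbolError

SYMBOLS_PER_WORD = 31
BITS_PER_SYMBOL = 2

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"
_RC_TABLE = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class PackedSeq:
    """A DNA string in 2-bit-per-symbol form across 64-bit words.

    Attributes
    ----------
    words:
        Tuple of non-negative integers, each < 2**63 (sign bit clear),
        holding up to 31 symbols apiece.
    length:
        Number of symbols encoded; ``len(words) == ceil(length / 31)``.
    """

    words: tuple[int, ...]
    length: int

    def __len__(self) -> int:
        return self.length

    def value(self) -> int:
        """The whole sequence as one big-endian 2-bit integer.

        Equal-length sequences compare (as integers) exactly as their
        decoded strings compare lexicographically.
        """
        n_last = self.length - (len(self.words) - 1) * SYMBOLS_PER_WORD
        v = 0
        for w in self.words[:-1]:
            v = (v << (BITS_PER_SYMBOL * SYMBOLS_PER_WORD)) | w
        v = (v << (BITS_PER_SYMBOL * n_last)) | self.words[-1]
        return v


def encode_symbol(base: str) -> int:
    """Map one of A/C/G/T to its 2-bit code (A=0, C=1, G=2, T=3)."""
    try:
        return _CODE[base]
    except KeyError:
        raise InvalidSymbolError(f"not an unambiguous DNA base: {base!r}") from None


def pack(seq: str) -> PackedSeq:
    """Pack an A/C/G/T string, 31 symbols per 64-bit word.

    The first symbol of each word sits in the highest occupied bit pair;
    the final word is left-padded with zeros.
    """
    if not seq:
        raise InvalidSymbolError("cannot pack an empty sequence")
    words = []
    for start in range(0, len(seq), SYMBOLS_PER_WORD):
        w = 0
        for base in seq[start : start + SYMBOLS_PER_WORD]:
            w = (w << BITS_PER_SYMBOL) | encode_symbol(base)
        words.append(w)
    return PackedSeq(words=tuple(words), length=len(seq))


def unpack(p: PackedSeq) -> str:
    """Decode a PackedSeq back to its A/C/G/T string (inverse of pack)."""
    expected_words = -(-p.length // SYMBOLS_PER_WORD)
    if len(p.words) != expected_words or p.length < 1:
        raise CorruptionError(
            f"length {p.length} implies {expected_words} words, got {len(p.words)}"
        )
    out = []
    remaining = p.length
    for w in p.words:
        n = min(remaining, SYMBOLS_PER_WORD)
        if w >> (BITS_PER_SYMBOL * n):
            raise CorruptionError("non-zero padding bits in packed word")
        chunk = [_BASE[(w >> (BITS_PER_SYMBOL * (n - 1 - i))) & 3] for i in range(n)]
        out.append("".join(chunk))
        remaining -= n
    return "".join(out)


def reverse_complement(seq):
    """Reverse-complement a string or PackedSeq (A<->T, C<->G, reversed)."""
    if isinstance(seq, PackedSeq):
        return pack(reverse_complement(unpack(seq)))
    return seq.translate(_RC_TABLE)[::-1]


def canonical(seq):
    """The lexicographic minimum (A<C<G<T) of a sequence and its reverse
    complement; the strand-neutral representative used throughout."""
    if isinstance(seq, PackedSeq):
        rc = reverse_complement(seq)
        return seq if seq.value() <= rc.value() else rc
    rc = seq.translate(_RC_TABLE)[::-1]
    return seq if seq <= rc else rc


def pack_value(seq: str) -> int:
    """The 2-bit big-endian integer value of a string, without word layout.

    Used as a hashable key for k-mers and signatures; for equal lengths,
    integer order equals lexicographic order.
    """
    v = 0
    for base in seq:
        v = (v << BITS_PER_SYMBOL) | encode_symbol(base)
    return v


def value_to_string(value: int, length: int) -> str:
    """Decode a 2-bit big-endian integer of `length` symbols to A/C/G/T."""
    return "".join(
        _BASE[(value >> (BITS_PER_SYMBOL * (length - 1 - i))) & 3]
        for i in range(length)
    )
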