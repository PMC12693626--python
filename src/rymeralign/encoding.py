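"""Bit encodings for kmers and their purine/pyrimidine (RY) projections.

Nucleotides are packed two bits per base (A=00, C=01, G=10, T=11) into an
unsigned integer, first base in the most significant occupied bits, so a
kmer of up to 31 bases fits in 62 bits.  The RY projection keeps only the
low-order bit of each 2-bit code: purines (A=00, G=10) map to 0 and
pyrimidines (C=01, T=11) map to 1, which makes the projection of a packed
kmer a pure bit-extraction.  RY keys may therefore be up to 62 bases long,
although in practice they share k with the kmer index they are derived from.

Deamination (C->T, G->A) is a transition and never changes the RY class of
a base, which is what makes RY space useful for seeding damaged reads.
"""

from __future__ import annotations

from typing import NamedTuple

__all__ = [
    "KmerKey",
    "RymerKey",
    "EncodingError",
    "encode_kmer",
    "decode_kmer",
    "ry_string",
    "encode_ry",
    "decode_ry",
    "kmer_key_to_rymer_key",
    "reverse_complement",
    "ry_reverse_complement",
]

MAX_KMER_LENGTH = 31
MAX_RYMER_LENGTH = 62

_BASE_TO_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS_TO_BASE = "ACGT"
_RC_TABLE = str.maketrans("ACGT", "TGCA")
_RY_TABLE = str.maketrans("AGCT", "RRYY")


class EncodingError(ValueError):
    """Raised for unencodable sequences or malformed keys."""


class KmerKey(NamedTuple):
    """Packed 2-bit nucleotide key. `k` is carried explicitly because the
    packing alone is length-ambiguous (leading A's are zero bits)."""

    bits: int
    k: int


class RymerKey(NamedTuple):
    """Packed 1-bit purine(0)/pyrimidine(1) key."""

    bits: int
    k: int


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    for ch in seq:
        if ch not in _BASE_TO_BITS:
            raise EncodingError(f"unencodable kmer: ambiguous base {ch!r}")
    return seq


def encode_kmer(seq: str) -> KmerKey:
    """Pack an ACGT string (len <= 31) into a :class:`KmerKey`."""
    seq = _validate_seq(seq)
    k = len(seq)
    if k == 0:
        raise EncodingError("unencodable kmer: empty sequence")
    if k > MAX_KMER_LENGTH:
        raise EncodingError(f"key overflow: k={k} > {MAX_KMER_LENGTH}")
    bits = 0
    for ch in seq:
        bits = (bits << 2) | _BASE_TO_BITS[ch]
    return KmerKey(bits, k)


def decode_kmer(key: KmerKey) -> str:
    """Inverse of :func:`encode_kmer`."""
    bits, k = key
    if not 1 <= k <= MAX_KMER_LENGTH:
        raise EncodingError(f"corrupt key: invalid k={k}")
    if bits >> (2 * k):
        raise EncodingError("corrupt key: high bits set")
    return "".join(_BITS_TO_BASE[(bits >> (2 * (k - 1 - i))) & 3] for i in range(k))


def ry_string(seq: str) -> str:
    """Project an ACGT string onto the two-letter R/Y alphabet."""
    return _validate_seq(seq).translate(_RY_TABLE)


def encode_ry(ry: str) -> RymerKey:
    """Pack an R/Y string (R=0, Y=1) into a :class:`RymerKey`."""
    k = len(ry)
    if k == 0 or k > MAX_RYMER_LENGTH:
        raise EncodingError(f"key overflow: RY length {k}")
    bits = 0
    for ch in ry:
        if ch == "R":
            bits <<= 1
        elif ch == "Y":
            bits = (bits << 1) | 1
        else:
            raise EncodingError(f"unencodable kmer: bad RY symbol {ch!r}")
    return RymerKey(bits, k)


def decode_ry(key: RymerKey) -> str:
    bits, k = key
    if not 1 <= k <= MAX_RYMER_LENGTH:
        raise EncodingError(f"corrupt key: invalid k={k}")
    if bits >> k:
        raise EncodingError("corrupt key: high bits set")
    return "".join("Y" if (bits >> (k - 1 - i)) & 1 else "R" for i in range(k))


def kmer_key_to_rymer_key(key: KmerKey) -> RymerKey:
    """Project a packed kmer key into RY space.

    The purine/pyrimidine class of a base is the low bit of its 2-bit code,
    so the projection just gathers every even-position bit of the packing.
    """
    bits, k = key
    if bits >> (2 * k):
        raise EncodingError("corrupt key: high bits set")
    ry = 0
    for i in range(k):
        ry = (ry << 1) | ((bits >> (2 * (k - 1 - i))) & 1)
    return RymerKey(ry, k)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string."""
    return _validate_seq(seq).translate(_RC_TABLE)[::-1]


def ry_reverse_complement(key: RymerKey) -> RymerKey:
    """Reverse complement in RY space: complementation swaps purine and
    pyrimidine, so this is bit-reversal followed by bit-flip."""
    bits, k = key
    if bits >> k:
        raise EncodingError("corrupt key: high bits set")
    out = 0
    for _ in range(k):
        out = (out << 1) | (bits & 1)
        bits >>= 1
    return RymerKey(out ^ ((1 << k) - 1), k)
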