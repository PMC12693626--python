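"""(w,k)-minimizer index over a haplotype panel, plus the derived RY index.

The minimizer index maps canonical packed kmer keys to their occurrence
list on the panel.  The RY index is NOT an independently winnowed index of
the RY-transformed panel: winnowing in RY space would select a different
kmer set and completeness would be lost.  Instead the minimizer set itself
is projected into RY space, so every indexed minimizer is reachable from
its RY key, and each RY key's value is the list of minimizer keys that
produced it (several minimizers can collapse onto one RY key).

Sequences flagged circular are indexed with a virtual wrap-around extension
and offsets reported modulo the original length, so the key set is
invariant under rotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO

from .encoding import (
    EncodingError,
    KmerKey,
    RymerKey,
    encode_kmer,
    kmer_key_to_rymer_key,
    reverse_complement,
)

__all__ = [
    "HaplotypePanel",
    "Hit",
    "MinimizerIndex",
    "RymerIndex",
    "IndexError_",
    "wang_hash",
    "select_minimizers",
    "build_minimizer_index",
    "build_rymer_index",
    "build_indexes",
    "lookup_minimizer",
    "lookup_rymer",
    "save_index",
    "load_index",
    "read_panel_fasta",
    "write_panel_fasta",
]

FORWARD = 0
REVERSE = 1

DEFAULT_K = 29
DEFAULT_W = 11

_MASK64 = (1 << 64) - 1


class IndexError_(ValueError):
    """Index construction / serialization / parameter errors."""


class Hit(NamedTuple):
    seq_id: int
    offset: int  # forward-strand 0-based start of the kmer occurrence
    orientation: int  # FORWARD if the canonical key reads off the forward strand


@dataclass
class HaplotypePanel:
    """An ordered set of named haplotype sequences, each optionally circular."""

    sequences: list[tuple[str, str, bool]]

    def __post_init__(self) -> None:
        names = [name for name, _, _ in self.sequences]
        if len(set(names)) != len(names):
            raise IndexError_("panel sequence names must be unique")
        for name, seq, _ in self.sequences:
            if not seq:
                raise IndexError_(f"panel sequence {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sequences)

    def names(self) -> list[str]:
        return [name for name, _, _ in self.sequences]

    def seq(self, seq_id: int) -> str:
        return self.sequences[seq_id][1]

    def is_circular(self, seq_id: int) -> bool:
        return self.sequences[seq_id][2]


@dataclass
class MinimizerIndex:
    k: int
    w: int
    table: dict[KmerKey, list[Hit]] = field(default_factory=dict)


@dataclass
class RymerIndex:
    k: int
    w: int
    table: dict[RymerKey, list[KmerKey]] = field(default_factory=dict)


def wang_hash(x: int) -> int:
    """Thomas Wang's 64-bit invertible integer mix.

    Fixed constants, no seed: two builds of the same panel are bit-identical.
    """
    x &= _MASK64
    x = (~x + (x << 21)) & _MASK64
    x ^= x >> 24
    x = (x + (x << 3) + (x << 8)) & _MASK64
    x ^= x >> 14
    x = (x + (x << 2) + (x << 4)) & _MASK64
    x ^= x >> 28
    x = (x + (x << 31)) & _MASK64
    return x


def _candidates(seq: str, k: int):
    """Per start position: (hash, canonical key, orientation) or None.

    The canonical form of a kmer is whichever of the forward kmer and its
    reverse complement has the smaller Wang hash (forward wins ties, which
    only arise for palindromes).
    """
    out: list[tuple[int, KmerKey, int] | None] = []
    n = len(seq)
    for i in range(n - k + 1):
        sub = seq[i : i + k]
        try:
            fwd = encode_kmer(sub)
            rev = encode_kmer(reverse_complement(sub))
        except EncodingError:
            out.append(None)
            continue
        hf, hr = wang_hash(fwd.bits), wang_hash(rev.bits)
        if hf <= hr:
            out.append((hf, fwd, FORWARD))
        else:
            out.append((hr, rev, REVERSE))
    return out


def select_minimizers(
    seq: str, k: int, w: int, circular: bool = False
) -> list[tuple[KmerKey, Hit]]:
    """Winnow a sequence: within every window of ``w`` consecutive kmer start
    positions pick the canonical kmer with the smallest hash (leftmost on
    ties).  Kmers containing ambiguous bases never compete.  For circular
    sequences both kmers and windows wrap and offsets are reported mod len.

    Returns each selected (key, hit) once, in order of first selection; the
    hit's seq_id is 0 and is rewritten by the panel-level builder.
    """
    seq = seq.upper()
    n = len(seq)
    if w < 1:
        raise IndexError_("window size w must be >= 1")
    if circular:
        if n < k:
            raise IndexError_("sequence too short for k even with wrap")
        ext = seq + seq[: k - 1 + w - 1]
        cands = _candidates(ext, k)[:n]  # starts 0..n-1, windows wrap below
        n_windows = n
    else:
        if n < k:
            raise IndexError_("sequence too short")
        cands = _candidates(seq, k)
        n_starts = len(cands)
        n_windows = max(1, n_starts - w + 1)

    selected: list[tuple[KmerKey, Hit]] = []
    seen: set[tuple[KmerKey, int, int]] = set()
    n_starts = len(cands)
    for win in range(n_windows):
        best = None
        for j in range(w):
            pos = win + j
            if circular:
                pos %= n_starts
            elif pos >= n_starts:
                break
            c = cands[pos]
            if c is None:
                continue
            if best is None or c[0] < best[0][0]:
                best = (c, pos)
        if best is None:
            continue
        (h, key, orient), pos = best
        offset = pos % n if circular else pos
        ident = (key, offset, orient)
        if ident not in seen:
            seen.add(ident)
            selected.append((key, Hit(0, offset, orient)))
    return selected


def build_minimizer_index(panel: HaplotypePanel, k: int, w: int) -> MinimizerIndex:
    """Winnow every haplotype and group hits by canonical key."""
    index = MinimizerIndex(k=k, w=w)
    for seq_id, (name, seq, circular) in enumerate(panel.sequences):
        try:
            sel = select_minimizers(seq, k, w, circular)
        except IndexError_ as exc:
            raise IndexError_(f"sequence {name!r}: {exc}") from exc
        for key, hit in sel:
            index.table.setdefault(key, []).append(hit._replace(seq_id=seq_id))
    return index


def build_rymer_index(min_index: MinimizerIndex) -> RymerIndex:
    """Project every minimizer key into RY space; the RY value lists the
    minimizer keys it came from, giving O(1) RY->minimizer recovery."""
    ry = RymerIndex(k=min_index.k, w=min_index.w)
    for key in min_index.table:
        rykey = kmer_key_to_rymer_key(key)
        bucket = ry.table.setdefault(rykey, [])
        if key not in bucket:
            bucket.append(key)
    return ry


def build_indexes(panel: HaplotypePanel, k: int = DEFAULT_K, w: int = DEFAULT_W):
    """Build the minimizer index and its derived RY index in one pass."""
    mi = build_minimizer_index(panel, k, w)
    return mi, build_rymer_index(mi)


def lookup_minimizer(index: MinimizerIndex, key: KmerKey) -> list[Hit]:
    if key.k != index.k:
        raise IndexError_(f"index parameter mismatch: key k={key.k}, index k={index.k}")
    return list(index.table.get(key, []))


def lookup_rymer(index: RymerIndex, rykey: RymerKey) -> list[KmerKey]:
    if rykey.k != index.k:
        raise IndexError_(f"index parameter mismatch: key k={rykey.k}, index k={index.k}")
    return list(index.table.get(rykey, []))


# ---------------------------------------------------------------------------
# serialization: a small line-based text format, one entry per line

_MIN_MAGIC = "RYMERALIGN-MIN\t1"
_RY_MAGIC = "RYMERALIGN-RY\t1"


def save_index(index: MinimizerIndex | RymerIndex, path: str | Path) -> None:
    path = Path(path)
    is_min = isinstance(index, MinimizerIndex)
    lines = [_MIN_MAGIC if is_min else _RY_MAGIC]
    lines.append(f"k\t{index.k}\tw\t{index.w}\tn\t{len(index.table)}")
    if is_min:
        for key, hits in index.table.items():
            body = ";".join(f"{h.seq_id},{h.offset},{h.orientation}" for h in hits)
            lines.append(f"{key.bits}\t{body}")
    else:
        for rykey, keys in index.table.items():
            body = ";".join(str(kk.bits) for kk in keys)
            lines.append(f"{rykey.bits}\t{body}")
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text("\n".join(lines) + "\n")
    tmp.replace(path)


def load_index(path: str | Path) -> MinimizerIndex | RymerIndex:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] not in (_MIN_MAGIC, _RY_MAGIC):
        raise IndexError_(f"unrecognized index file: {path}")
    is_min = lines[0] == _MIN_MAGIC
    if len(lines) < 2:
        raise IndexError_(f"corrupt index: {path}")
    hdr = lines[1].split("\t")
    try:
        k, w, n = int(hdr[1]), int(hdr[3]), int(hdr[5])
    except (IndexError, ValueError) as exc:
        raise IndexError_(f"corrupt index: {path}") from exc
    entries = lines[2:]
    if len(entries) != n:
        raise IndexError_(f"corrupt index: {path} (truncated)")
    if is_min:
        mi = MinimizerIndex(k=k, w=w)
        for line in entries:
            bits_s, body = line.split("\t")
            hits = []
            for part in body.split(";"):
                s, o, r = part.split(",")
                hits.append(Hit(int(s), int(o), int(r)))
            mi.table[KmerKey(int(bits_s), k)] = hits
        return mi
    ry = RymerIndex(k=k, w=w)
    for line in entries:
        bits_s, body = line.split("\t")
        ry.table[RymerKey(int(bits_s), k)] = [KmerKey(int(p), k) for p in body.split(";")]
    return ry


# ---------------------------------------------------------------------------
# panel I/O

def read_panel_fasta(
    path: str | Path, circular: Iterable[str] | bool | None = None
) -> HaplotypePanel:
    """Read a haplotype panel from FASTA.

    Circularity is declared either by passing a collection of record names
    (or True for all), or per record with a ``circular=true`` token in the
    FASTA description line.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise IndexError_(f"no sequences in {path}")
    circ_names: set[str] | None
    if circular is True:
        circ_names = {r.id for r in records}
    elif circular:
        circ_names = set(circular)
    else:
        circ_names = set()
    seqs = []
    for r in records:
        is_circ = r.id in circ_names or "circular=true" in r.description.lower()
        seqs.append((r.id, str(r.seq).upper(), is_circ))
    return HaplotypePanel(seqs)


def write_panel_fasta(panel: HaplotypePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, circular in panel.sequences:
            desc = " circular=true" if circular else ""
            fh.write(f">{name}{desc}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
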