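"""Synthetic ancient-DNA benchmark generator with machine-readable truth.

Datasets emulate a mitochondrial-style experiment: short endogenous
fragments drawn from a (usually circular) haplotype, deaminated at the
fragment ends according to a damage profile; NuMT-like decoy reads drawn
from diverged copies of the endogenous sequence embedded in random host
background; and unrelated contaminant reads from random sequence.  Base
qualities are constant 'I' — no sequencing-error model, matching the
filter's scope.  Every read carries its provenance in a truth table so the
evaluation harness can score alignments as a binary classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .damage import DamagePattern, DamageProfile, make_parametric_profile
from .encoding import reverse_complement
from .indexing import HaplotypePanel

__all__ = [
    "FragmentLengthSpec",
    "SimulatedRead",
    "SimulationConfig",
    "generate_panel",
    "random_sequence",
    "sample_fragments",
    "apply_damage",
    "make_numt_decoys",
    "simulate_dataset",
    "write_truth",
    "load_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

TRUTH_COLUMNS = [
    "name", "truth_class", "truth_seq_id", "truth_start", "truth_strand",
    "fragment_length", "n_damage_events",
]


@dataclass
class FragmentLengthSpec:
    """Fragment length distribution: log-normal by default, or an explicit
    empirical length->weight table (loadable from two-column TSV)."""

    mean_log: float = np.log(42.0)
    sd_log: float = 0.3
    min_len: int = 30
    max_len: int = 120
    table: dict[int, float] | None = None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FragmentLengthSpec":
        df = pd.read_csv(path, sep="\t", header=None, names=["length", "weight"],
                         comment="#")
        table = {int(l): float(w) for l, w in zip(df["length"], df["weight"])}
        if not table or any(w < 0 for w in table.values()) or sum(table.values()) == 0:
            raise ValueError("invalid fragment length table")
        return cls(min_len=min(table), max_len=max(table), table=table)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.table is not None:
            lengths = np.array(sorted(self.table))
            w = np.array([self.table[l] for l in lengths], dtype=float)
            return rng.choice(lengths, size=n, p=w / w.sum())
        out = np.empty(n, dtype=int)
        filled = 0
        while filled < n:
            draw = rng.lognormal(self.mean_log, self.sd_log, size=n - filled)
            draw = draw[(draw >= self.min_len) & (draw <= self.max_len)].astype(int)
            out[filled : filled + len(draw)] = draw
            filled += len(draw)
        return out


@dataclass
class SimulatedRead:
    name: str
    sequence: str
    truth_class: str  # endogenous | numt | contaminant
    truth_seq_id: str | None
    truth_start: int | None
    truth_strand: str | None
    fragment_length: int
    damage_events: list[tuple[int, str, str]] = field(default_factory=list)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """i.i.d. substitutions at the given per-site rate (uniform over the
    three alternatives)."""
    if divergence == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < divergence
    for i in np.flatnonzero(hit):
        alts = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([rng.choice(alts)])
    return arr.tobytes().decode()


def generate_panel(
    n_haplotypes: int,
    genome_length: int,
    divergence: float,
    circular: bool = True,
    seed: int | np.random.Generator = 0,
) -> tuple[HaplotypePanel, str]:
    """Random ancestral sequence plus haplotypes derived from it by i.i.d.
    substitution at the stated rate.  Returns (panel, ancestral)."""
    if not 0 <= divergence <= 0.2:
        raise ValueError("divergence must be in [0, 0.2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ancestral = random_sequence(genome_length, rng)
    seqs = [
        (f"hap{i}", _mutate(ancestral, divergence, rng), circular)
        for i in range(n_haplotypes)
    ]
    return HaplotypePanel(seqs), ancestral


def sample_fragments(
    source_seq: str,
    n: int,
    fls: FragmentLengthSpec,
    seed: int | np.random.Generator = 0,
    circular: bool = True,
    max_retries: int = 50,
) -> list[tuple[int, int, int]]:
    """Draw (start, length, strand) triples: uniform starts (wrapping when
    circular), fair-coin strand, lengths i.i.d. from the spec."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(source_seq)
    out = []
    for _ in range(n):
        length = None
        for _ in range(max_retries):
            cand = int(fls.sample(1, rng)[0])
            if circular or cand <= L:
                length = cand
                break
        if length is None:
            raise ValueError("fragment longer than linear sequence after retries")
        if circular:
            start = int(rng.integers(0, L))
        else:
            start = int(rng.integers(0, L - length + 1))
        strand = int(rng.integers(0, 2))
        out.append((start, length, strand))
    return out


def extract_fragment(source_seq: str, start: int, length: int, strand: int,
                     circular: bool = True) -> str:
    L = len(source_seq)
    if circular:
        frag = "".join(source_seq[(start + i) % L] for i in range(length))
    else:
        frag = source_seq[start : start + length]
    return frag if strand == 0 else reverse_complement(frag)


def apply_damage(
    fragment: str,
    profile: DamageProfile,
    seed: int | np.random.Generator = 0,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Deaminate a fragment in its sequenced orientation: each C becomes T
    with probability delta(C>T) at its position, each G becomes A with
    delta(G>A).  Returns the damaged sequence and the event list."""
    from .damage import delta

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(fragment)
    out = list(fragment)
    events = []
    for i, base in enumerate(fragment):
        pos3 = L - 1 - i
        if base == "C":
            rate = delta(profile, "C>T", i, pos3, L)
            if rate > 0 and rng.random() < rate:
                out[i] = "T"
                events.append((i, "C", "T"))
        elif base == "G":
            rate = delta(profile, "G>A", i, pos3, L)
            if rate > 0 and rng.random() < rate:
                out[i] = "A"
                events.append((i, "G", "A"))
    return "".join(out), events


def make_numt_decoys(
    mito_seq: str,
    n: int,
    divergence: float,
    insert_host_length: int = 2000,
    segment_length: tuple[int, int] = (300, 1500),
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, int, int]]:
    """NuMT-like decoys: a random mitochondrial segment, mutated at the
    stated divergence, embedded in random host sequence.  Returns
    (decoy sequence, segment start within decoy, segment length)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(mito_seq)
    decoys = []
    for _ in range(n):
        seg_len = int(rng.integers(segment_length[0], min(segment_length[1], L) + 1))
        start = int(rng.integers(0, L))
        segment = "".join(mito_seq[(start + i) % L] for i in range(seg_len))
        segment = _mutate(segment, divergence, rng)
        host_left = int(rng.integers(0, insert_host_length + 1))
        host_right = insert_host_length - host_left
        decoy = (
            random_sequence(host_left, rng) + segment + random_sequence(host_right, rng)
        )
        decoys.append((decoy, host_left, seg_len))
    return decoys


@dataclass
class SimulationConfig:
    """Composition and conditions of one synthetic dataset."""

    n_endogenous: int = 2000
    n_contaminant: int = 1000
    n_numt_reads: int = 0
    n_numts: int = 4
    panel_haplotypes: int = 1
    genome_length: int = 10000
    panel_divergence: float = 0.0
    circular: bool = True
    numt_divergence: float = 0.05
    contaminant_genome_length: int = 50000
    damage_pattern: DamagePattern | str = DamagePattern.DOUBLE_STRANDED_HIGH
    fls: FragmentLengthSpec = field(default_factory=FragmentLengthSpec)
    error_rate: float = 0.0  # optional uniform substitution error, off by default

    def __post_init__(self) -> None:
        for name in ("n_endogenous", "n_contaminant", "n_numt_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def simulate_dataset(
    config: SimulationConfig, seed: int = 0, profile: DamageProfile | None = None
) -> tuple[HaplotypePanel, list[SimulatedRead], DamageProfile]:
    """Generate the panel and the full read set, deterministically per seed.

    Endogenous fragments come from haplotype 0 and are deaminated; NuMT and
    contaminant reads are modern (undamaged).  Returns (panel, reads,
    damage profile used).
    """
    rng = np.random.default_rng(seed)
    if profile is None:
        profile = make_parametric_profile(config.damage_pattern)
    panel, _ = generate_panel(
        config.panel_haplotypes,
        config.genome_length,
        config.panel_divergence,
        circular=config.circular,
        seed=rng,
    )
    source = panel.seq(0)
    reads: list[SimulatedRead] = []

    frags = sample_fragments(
        source, config.n_endogenous, config.fls, rng, circular=config.circular
    )
    for i, (start, length, strand) in enumerate(frags):
        frag = extract_fragment(source, start, length, strand, config.circular)
        damaged, events = apply_damage(frag, profile, rng)
        damaged = _with_errors(damaged, config.error_rate, rng)
        reads.append(
            SimulatedRead(
                name=f"endo_{i}",
                sequence=damaged,
                truth_class="endogenous",
                truth_seq_id=panel.names()[0],
                truth_start=start,
                truth_strand="-" if strand else "+",
                fragment_length=length,
                damage_events=events,
            )
        )

    if config.n_numt_reads > 0:
        decoys = make_numt_decoys(
            source, config.n_numts, config.numt_divergence, seed=rng
        )
        per = np.array_split(np.arange(config.n_numt_reads), len(decoys))
        for d, idxs in enumerate(per):
            decoy, _, _ = decoys[d]
            dfrags = sample_fragments(
                decoy, len(idxs), config.fls, rng, circular=False
            )
            for j, (start, length, strand) in zip(idxs, dfrags):
                frag = extract_fragment(decoy, start, length, strand, circular=False)
                frag = _with_errors(frag, config.error_rate, rng)
                reads.append(
                    SimulatedRead(
                        name=f"numt_{j}",
                        sequence=frag,
                        truth_class="numt",
                        truth_seq_id=None,
                        truth_start=None,
                        truth_strand=None,
                        fragment_length=length,
                    )
                )

    if config.n_contaminant > 0:
        contaminant = random_sequence(config.contaminant_genome_length, rng)
        cfrags = sample_fragments(
            contaminant, config.n_contaminant, config.fls, rng, circular=False
        )
        for i, (start, length, strand) in enumerate(cfrags):
            frag = extract_fragment(contaminant, start, length, strand, circular=False)
            frag = _with_errors(frag, config.error_rate, rng)
            reads.append(
                SimulatedRead(
                    name=f"cont_{i}",
                    sequence=frag,
                    truth_class="contaminant",
                    truth_seq_id=None,
                    truth_start=None,
                    truth_strand=None,
                    fragment_length=length,
                )
            )

    return panel, reads, profile


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    return _mutate(seq, rate, rng)


def write_fastq(reads: list[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth(reads: list[SimulatedRead], path: str | Path) -> None:
    rows = [
        {
            "name": r.name,
            "truth_class": r.truth_class,
            "truth_seq_id": r.truth_seq_id if r.truth_seq_id is not None else ".",
            "truth_start": r.truth_start if r.truth_start is not None else ".",
            "truth_strand": r.truth_strand if r.truth_strand is not None else ".",
            "fragment_length": r.fragment_length,
            "n_damage_events": len(r.damage_events),
        }
        for r in reads
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def load_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"truth_start": str})
    return df
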