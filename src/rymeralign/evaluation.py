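"""Benchmark scoring: binary-classification metrics and damage-rate recovery.

Mapping is scored as a binary classification: an endogenous read is a true
positive when its reported position falls within 50 bp of the true locus
(circular distance on circular references) and a false negative otherwise —
an endogenous read mapped elsewhere is still a false negative, never a
false positive.  NuMT and contaminant reads are negatives: true negatives
when unmapped, false positives when mapped.

Damage-rate recovery re-estimates the per-position substitution matrices
from alignments, bam2prof-style: for each of the first L positions from
each fragment end (strand-corrected), the rate of X>Y is the fraction of
aligned reference-X sites observed as Y.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .damage import SUBSTITUTIONS, DamageProfile, _SUB_INDEX
from .encoding import reverse_complement
from .indexing import HaplotypePanel

__all__ = [
    "ConfusionCounts",
    "classify_read",
    "compute_metrics",
    "evaluate_sam",
    "estimate_damage_profile",
    "rmse_profiles",
]

DEFAULT_TOLERANCE = 50


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _circular_distance(a: int, b: int, length: int) -> int:
    d = abs(a - b) % length
    return min(d, length - d)


def classify_read(
    truth_class: str,
    truth_start: int | None,
    mapped_start: int | None,
    ref_length: int | None = None,
    circular: bool = False,
    tolerance: int = DEFAULT_TOLERANCE,
) -> str:
    """Classify one read into TP/FP/TN/FN under the 50-bp correctness rule."""
    if truth_class == "endogenous":
        if mapped_start is None:
            return "FN"
        if circular and ref_length:
            dist = _circular_distance(mapped_start, truth_start, ref_length)
        else:
            dist = abs(mapped_start - truth_start)
        return "TP" if dist <= tolerance else "FN"
    return "TN" if mapped_start is None else "FP"


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, F1); NaN with a warning on an undefined
    (zero-denominator) metric."""
    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator")
            return math.nan
        return num / den

    sens = _ratio(counts.TP, counts.TP + counts.FN, "sensitivity")
    spec = _ratio(counts.TN, counts.TN + counts.FP, "specificity")
    f1 = _ratio(2 * counts.TP, 2 * counts.TP + counts.FP + counts.FN, "F1")
    return sens, spec, f1


def evaluate_sam(
    sam_path: str | Path,
    truth: pd.DataFrame,
    panel: HaplotypePanel,
    tolerance: int = DEFAULT_TOLERANCE,
    min_mapq: int = 0,
) -> tuple[ConfusionCounts, pd.DataFrame]:
    """Score a SAM file against a truth table.

    Any primary alignment (with MAPQ >= min_mapq, default 0) counts as
    mapped.  Returns the confusion counts and a per-read outcome table.
    """
    mapped: dict[str, tuple[str, int]] = {}
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            mapped[rec.query_name] = (rec.reference_name, rec.reference_start)

    name_to_len = {name: len(seq) for name, seq, _ in panel.sequences}
    name_to_circ = {name: circ for name, _, circ in panel.sequences}

    counts = ConfusionCounts()
    outcomes = []
    truth_names = set(truth["name"])
    for rec_name in mapped:
        if rec_name not in truth_names:
            raise KeyError(f"unknown read: {rec_name!r} not in truth table")
    for row in truth.itertuples(index=False):
        hit = mapped.get(row.name)
        mapped_start = None
        correct_ref = True
        if hit is not None:
            ref_name, mapped_start = hit
            if row.truth_class == "endogenous" and ref_name != row.truth_seq_id:
                correct_ref = False
        if row.truth_class == "endogenous":
            ts = int(row.truth_start)
            rl = name_to_len.get(row.truth_seq_id)
            circ = name_to_circ.get(row.truth_seq_id, False)
            if not correct_ref:
                outcome = "FN"
            else:
                outcome = classify_read(
                    "endogenous", ts, mapped_start, rl, circ, tolerance
                )
        else:
            outcome = classify_read(row.truth_class, None, mapped_start)
        setattr(counts, outcome, getattr(counts, outcome) + 1)
        outcomes.append({"name": row.name, "outcome": outcome})
    return counts, pd.DataFrame(outcomes)


def estimate_damage_profile(
    sam_path: str | Path, panel: HaplotypePanel, L: int = 10
) -> DamageProfile:
    """bam2prof-style substitution-frequency estimate from alignments.

    Counts, at each of the first/last ``L`` aligned positions in original
    fragment orientation, observed base against reference base; reverse
    alignments are flipped back so position 0 is always the fragment's
    5' end.  Positions with no aligned source base get rate 0.
    """
    sub_counts5 = np.zeros((L, len(SUBSTITUTIONS)))
    src_counts5 = np.zeros((L, 4))
    sub_counts3 = np.zeros((L, len(SUBSTITUTIONS)))
    src_counts3 = np.zeros((L, 4))
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    n_alignments = 0
    name_to_id = {name: i for i, (name, _, _) in enumerate(panel.sequences)}
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            n_alignments += 1
            seq_id = name_to_id[rec.reference_name]
            ref_seq = panel.seq(seq_id)
            circ = panel.is_circular(seq_id)
            ref_len = len(ref_seq)
            read = rec.query_sequence  # reference-forward orientation
            cigar = rec.cigartuples or []
            qpos, rpos = 0, rec.reference_start
            pairs = []  # (query position, read base, ref base)
            for op, length in cigar:
                if op == pysam.CMATCH:
                    for i in range(length):
                        rp = (rpos + i) % ref_len if circ else rpos + i
                        if 0 <= rp < ref_len:
                            pairs.append((qpos + i, read[qpos + i], ref_seq[rp]))
                    qpos += length
                    rpos += length
                elif op == pysam.CSOFT_CLIP:
                    qpos += length
            if not pairs:
                continue
            n = len(read)
            if rec.is_reverse:
                # back to sequenced-fragment coordinates and bases
                pairs = [
                    (n - 1 - q, reverse_complement(b), reverse_complement(g))
                    for q, b, g in pairs
                ]
            for i, b, g in pairs:
                if b not in base_idx or g not in base_idx:
                    continue
                pos3 = n - 1 - i
                if i < L:
                    src_counts5[i, base_idx[g]] += 1
                    if b != g:
                        sub_counts5[i, _SUB_INDEX[f"{g}>{b}"]] += 1
                if pos3 < L:
                    src_counts3[pos3, base_idx[g]] += 1
                    if b != g:
                        sub_counts3[pos3, _SUB_INDEX[f"{g}>{b}"]] += 1

    if n_alignments == 0:
        raise ValueError("no alignments to estimate a damage profile from")

    def _rates(sub_counts: np.ndarray, src_counts: np.ndarray) -> np.ndarray:
        rates = np.zeros_like(sub_counts)
        for j, sub in enumerate(SUBSTITUTIONS):
            src = base_idx[sub[0]]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(
                    src_counts[:, src] > 0, sub_counts[:, j] / src_counts[:, src], 0.0
                )
            rates[:, j] = r
        return rates

    return DamageProfile(_rates(sub_counts5, src_counts5), _rates(sub_counts3, src_counts3))


def rmse_profiles(estimated: DamageProfile, truth: DamageProfile) -> float:
    """Root mean squared cell-wise difference over both end matrices."""
    if (
        estimated.five_prime.shape != truth.five_prime.shape
        or estimated.three_prime.shape != truth.three_prime.shape
    ):
        raise ValueError("profile shape mismatch")
    diff = np.concatenate(
        [
            (estimated.five_prime - truth.five_prime).ravel(),
            (estimated.three_prime - truth.three_prime).ravel(),
        ]
    )
    return float(np.sqrt(np.mean(diff**2)))
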