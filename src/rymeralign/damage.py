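"""Position-dependent deamination rate profiles.

Post-mortem hydrolytic deamination converts cytosine to uracil, which is
sequenced as thymine.  The substitution rate decays roughly exponentially
with distance from the fragment end: double-stranded library preparations
show C->T at the 5' end and the complementary G->A at the 3' end, while
single-stranded preparations show C->T at both ends.

A profile holds two rate matrices (one per fragment end), rows indexed by
distance from that end and the 12 ordered substitution types as columns —
the same column-level layout as bam2prof-style ``.prof`` files.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SUBSTITUTIONS",
    "DamageProfile",
    "DamagePattern",
    "DamageError",
    "load_profile",
    "write_profile",
    "delta",
    "make_parametric_profile",
]

#: The 12 ordered substitution types, fixed alphabetical column order.
SUBSTITUTIONS = (
    "A>C", "A>G", "A>T",
    "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T",
    "T>A", "T>C", "T>G",
)
_SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTIONS)}

_TOL = 1e-9


class DamageError(ValueError):
    pass


class DamagePattern(str, enum.Enum):
    """Named damage regimes used throughout the benchmark harness."""

    NONE = "none"
    SINGLE_STRANDED = "single_stranded"
    DOUBLE_STRANDED_MID = "double_stranded_mid"
    DOUBLE_STRANDED_HIGH = "double_stranded_high"


@dataclass
class DamageProfile:
    """Per-position substitution rates from each fragment end.

    ``five_prime[i, j]`` is the rate of substitution ``SUBSTITUTIONS[j]`` at
    distance ``i`` from the 5' end; ``three_prime`` counts from the 3' end.
    """

    five_prime: np.ndarray
    three_prime: np.ndarray
    library_type: str = "double_stranded"

    def __post_init__(self) -> None:
        self.five_prime = np.asarray(self.five_prime, dtype=float)
        self.three_prime = np.asarray(self.three_prime, dtype=float)
        for name, mat in (("five_prime", self.five_prime), ("three_prime", self.three_prime)):
            if mat.ndim != 2 or mat.shape[1] != len(SUBSTITUTIONS):
                raise DamageError(f"malformed profile: {name} must have 12 columns")
            if (mat < -_TOL).any() or (mat > 1 + _TOL).any():
                raise DamageError("invalid rate: entries must lie in [0, 1]")
            np.clip(mat, 0.0, 1.0, out=mat)
            # per source base, the three outgoing rates cannot exceed 1
            for src in range(4):
                if (mat[:, 3 * src : 3 * src + 3].sum(axis=1) > 1 + _TOL).any():
                    raise DamageError("invalid rate: source-base rates sum over 1")

    @property
    def n_positions(self) -> tuple[int, int]:
        return self.five_prime.shape[0], self.three_prime.shape[0]

    def rate(self, end: str, pos: int, sub: str) -> float:
        mat = self.five_prime if end == "5p" else self.three_prime
        return float(mat[min(pos, mat.shape[0] - 1), _SUB_INDEX[sub]])


def load_profile(path_5p: str | Path, path_3p: str | Path,
                 library_type: str = "double_stranded") -> DamageProfile:
    """Read the two end matrices from tab-separated files.

    Each file carries a header row naming the 12 substitution columns and
    one row per position; ``#``-prefixed lines are ignored.
    """
    mats = []
    for path in (path_5p, path_3p):
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = [s for s in SUBSTITUTIONS if s not in df.columns]
        if missing:
            raise DamageError(f"malformed profile {path}: missing columns {missing}")
        mats.append(df[list(SUBSTITUTIONS)].to_numpy(dtype=float))
    return DamageProfile(mats[0], mats[1], library_type=library_type)


def write_profile(profile: DamageProfile, path_5p: str | Path, path_3p: str | Path) -> None:
    """Emit the TSV dialect that :func:`load_profile` reads."""
    for mat, path in ((profile.five_prime, path_5p), (profile.three_prime, path_3p)):
        pd.DataFrame(mat, columns=list(SUBSTITUTIONS)).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def delta(profile: DamageProfile, sub: str, pos5: int, pos3: int,
          fragment_length: int) -> float:
    """Deamination rate for substitution ``sub`` at a fragment position.

    ``pos5``/``pos3`` are the distances from the 5' and 3' ends
    (pos5 + pos3 == fragment_length - 1).  The nearer end's matrix is used
    (5' on ties); positions beyond the profiled range clamp to the last row.
    """
    if sub not in _SUB_INDEX:
        raise DamageError(f"invalid substitution: {sub!r}")
    if pos5 < 0 or pos3 < 0 or pos5 + pos3 != fragment_length - 1:
        raise DamageError("inconsistent fragment coordinates")
    if pos5 <= pos3:
        return profile.rate("5p", pos5, sub)
    return profile.rate("3p", pos3, sub)


def make_parametric_profile(
    pattern: DamagePattern | str,
    d_max: float | None = None,
    d_base: float = 0.01,
    lam: float = 0.7,
    L: int = 10,
) -> DamageProfile:
    """Synthetic stand-in profile with the canonical exponential end decay.

    The damage rate at distance ``i`` from the affected end is
    ``d_base + (d_max - d_base) * lam**i``.  Double-stranded patterns place
    C>T at the 5' end and the mirrored G>A at the 3' end; the
    single-stranded pattern places C>T at both ends; ``none`` is all zeros.

    Default ``d_max`` per pattern: 0.0 (none), 0.15 (single-stranded),
    0.2 (double-stranded mid), 0.5 (double-stranded high).
    """
    pattern = DamagePattern(pattern)
    defaults = {
        DamagePattern.NONE: 0.0,
        DamagePattern.SINGLE_STRANDED: 0.15,
        DamagePattern.DOUBLE_STRANDED_MID: 0.2,
        DamagePattern.DOUBLE_STRANDED_HIGH: 0.5,
    }
    if d_max is None:
        d_max = defaults[pattern]
    if pattern is DamagePattern.NONE:
        d_max, d_base = 0.0, 0.0
    if not (0 <= d_base <= d_max <= 1) or not (0 < lam < 1) or L < 1:
        raise DamageError("invalid damage parameters")

    decay = d_base + (d_max - d_base) * lam ** np.arange(L)
    five = np.zeros((L, len(SUBSTITUTIONS)))
    three = np.zeros((L, len(SUBSTITUTIONS)))
    if pattern is DamagePattern.SINGLE_STRANDED:
        five[:, _SUB_INDEX["C>T"]] = decay
        three[:, _SUB_INDEX["C>T"]] = decay
        lib = "single_stranded"
    elif pattern in (DamagePattern.DOUBLE_STRANDED_MID, DamagePattern.DOUBLE_STRANDED_HIGH):
        five[:, _SUB_INDEX["C>T"]] = decay
        three[:, _SUB_INDEX["G>A"]] = decay
        lib = "double_stranded"
    else:
        lib = "double_stranded"
    return DamageProfile(five, three, library_type=lib)
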