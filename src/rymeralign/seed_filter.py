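"""Bayesian accept/reject rule for seeds that match only in RY space.

When a read kmer is absent from the minimizer index but its RY projection
hits the RY index, the kmer-space sequences disagree at one or more
positions — necessarily transitions, since the RY classes agree.  Two
explanations compete: the seed is genuine but deaminated (model M), or the
RY agreement is incidental (model not-M).  The filter computes

    P(M | r) = P(r|M) P(M) / (P(r|M) P(M) + P(r|notM) P(notM))

and keeps the seed when the posterior clears a user threshold (``-j``).

P(r|M) multiplies, over the seed's bases, the deamination rate delta for a
damage-consistent mismatch (read T against reference C near the 5' end,
read A against reference G near the 3' end), (1 - delta) for an agreeing
deamination-prone base, 1 for agreeing bases that cannot deaminate, and 0
for a reverse-transition mismatch — such seeds can never be rescued.
Sequencing error is deliberately not modelled.

P(r|notM) is binomial in the mismatch count with per-base mismatch
probability p = a * k**b, capped at a small constant for long seeds where
the power law is no longer a good description (k >= 22 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .damage import DamageProfile, delta

__all__ = [
    "FilterParams",
    "SeedComparison",
    "spurious_likelihood",
    "damage_likelihood",
    "posterior",
    "filter_candidates",
    "fit_spurious_model",
]

# Defaults for the spurious power law, from fit_spurious_model: conditioned
# on RY-space equality of unrelated kmers each base mismatches independently
# with probability 1/2 (two nucleotides per RY class), independent of k.
DEFAULT_SPURIOUS_A = 0.5
DEFAULT_SPURIOUS_B = 0.0


@dataclass
class FilterParams:
    """Tunables of the rescue filter.

    prior_M : prior that a RY-space match is genuine-but-deaminated (-V).
    threshold_j : posterior needed for a seed to survive (-j).
    a, b : power-law coefficients of the spurious mismatch probability.
    k_cap, capped_likelihood : above k_cap the spurious likelihood is the
        flat constant instead of the binomial.
    """

    prior_M: float = 0.5
    threshold_j: float = 0.5
    a: float = DEFAULT_SPURIOUS_A
    b: float = DEFAULT_SPURIOUS_B
    k_cap: int = 22
    capped_likelihood: float = 0.01

    def __post_init__(self) -> None:
        for name in ("prior_M", "threshold_j", "capped_likelihood"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.a <= 0:
            raise ValueError("invalid spurious model parameters: a must be > 0")


class SeedComparison(NamedTuple):
    """A read kmer against the indexed kmer it matched in RY space.

    Both kmers are given in the read's own orientation (for reverse seeds
    the indexed kmer has been reverse-complemented first), so deamination
    always presents as read-T-vs-index-C or read-A-vs-index-G and fragment
    positions are plain read coordinates.
    """

    read_kmer: str
    index_kmer: str
    m: int
    pos5_of_kmer_start: int
    read_length: int
    orientation: int = 0


def spurious_likelihood(k: int, m: int, params: FilterParams | None = None) -> float:
    """P(r|notM): binomial PMF of m mismatches under p = a*k**b, or the flat
    cap for k >= k_cap."""
    params = params or FilterParams()
    if not 0 <= m <= k:
        raise ValueError(f"mismatch count m={m} outside 0..{k}")
    if k >= params.k_cap:
        return params.capped_likelihood
    p = params.a * k**params.b
    if not 0.0 < p < 1.0:
        raise ValueError(f"invalid spurious model parameters: p={p} outside (0,1)")
    return float(stats.binom.pmf(m, k, p))


def damage_likelihood(cmp: SeedComparison, profile: DamageProfile) -> float:
    """P(r|M): product over the seed's bases of the per-base deamination
    case probabilities, positioned within the fragment."""
    k = len(cmp.read_kmer)
    if len(cmp.index_kmer) != k:
        raise ValueError("seed and hit kmers differ in length")
    L = cmp.read_length
    prob = 1.0
    for i, (b, bg) in enumerate(zip(cmp.read_kmer, cmp.index_kmer)):
        pos5 = cmp.pos5_of_kmer_start + i
        pos3 = L - 1 - pos5
        if b == bg:
            if bg == "C":
                prob *= 1.0 - delta(profile, "C>T", pos5, pos3, L)
            elif bg == "G":
                prob *= 1.0 - delta(profile, "G>A", pos5, pos3, L)
        elif b == "T" and bg == "C":
            prob *= delta(profile, "C>T", pos5, pos3, L)
        elif b == "A" and bg == "G":
            prob *= delta(profile, "G>A", pos5, pos3, L)
        else:
            return 0.0
        if prob == 0.0:
            return 0.0
    return prob


def posterior(cmp: SeedComparison, profile: DamageProfile,
              params: FilterParams | None = None) -> float:
    """P(M|r) by exact Bayes; 0 when both likelihoods vanish."""
    params = params or FilterParams()
    k = len(cmp.read_kmer)
    like_m = damage_likelihood(cmp, profile)
    like_not = spurious_likelihood(k, cmp.m, params)
    num = like_m * params.prior_M
    den = num + like_not * (1.0 - params.prior_M)
    if den == 0.0:
        return 0.0
    return num / den


def filter_candidates(
    candidates: Sequence[SeedComparison],
    profile: DamageProfile,
    params: FilterParams | None = None,
) -> list[tuple[SeedComparison, float]]:
    """Keep candidates whose posterior clears threshold_j, order preserved."""
    params = params or FilterParams()
    out = []
    for cand in candidates:
        post = posterior(cand, profile, params)
        if post >= params.threshold_j:
            out.append((cand, post))
    return out


def fit_spurious_model(
    k_range: Sequence[int] = tuple(range(8, 22)),
    n_pairs: int = 20000,
    seed: int = 0,
) -> tuple[float, float]:
    """Fit the spurious power law p = a*k**b by simulation.

    Draws unrelated kmer pairs conditioned on RY-space equality (each base
    of the second kmer is uniform over the two nucleotides of the first
    base's RY class), records per-k mismatch fractions and least-squares
    fits the power law.  Conditioning makes the per-base mismatch
    probability exactly 1/2, so the fit converges to (0.5, 0.0).
    """
    rng = np.random.default_rng(seed)
    ks = np.asarray(k_range, dtype=float)
    fractions = []
    for k in k_range:
        first = rng.integers(0, 4, size=(n_pairs, k))
        # same RY class: flip the high bit (A<->G, C<->T) with prob 1/2
        second = first ^ (rng.integers(0, 2, size=(n_pairs, k)) << 1)
        fractions.append(float((first != second).mean()))
    frac = np.asarray(fractions)

    def residuals(theta):
        a, b = theta
        return a * ks**b - frac

    fit = optimize.least_squares(residuals, x0=[0.5, 0.0])
    return float(fit.x[0]), float(fit.x[1])
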