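# Methods

## Model

A read seed that matches the index in purine/pyrimidine (RY) space but not
in nucleotide space is explained by exactly one of two hypotheses: the seed
is genuine and was hit by deamination (M), or the RY agreement is
coincidence (¬M). Because complementary RY classes swap under
reverse-complementation, every kmer-space mismatch under an RY match is a
transition; the deamination-consistent transitions are read-T over
reference-C (5′-type) and read-A over reference-G (3′-type), and the
reverse transitions (read-C over T, read-G over A) have likelihood zero
under M — such seeds can never be rescued, whatever the parameters.

The damage likelihood multiplies per-base case probabilities over the k
seed bases only, positioned inside the fragment via the seed's read offset.
Both kmers are compared in the read's own orientation (the indexed kmer is
reverse-complemented first for reverse-orientation seeds). Since the
sequenced read *is* the fragment and deamination presents as C→T/G→A on the
sequenced strand, this frame makes the case analysis orientation-free and
read coordinates equal fragment coordinates; no substitution-type swap
table is needed. Agreeing C or G bases contribute (1 − δ) for the
deamination they escaped; bases that cannot deaminate contribute 1.
Sequencing error is deliberately out of scope of the model.

The spurious likelihood is binomial in the mismatch count with per-base
mismatch probability p = a·k^b, flattened to the constant 0.01 for k ≥ 22
where a power law no longer describes the tail. The default (a, b) =
(0.5, 0.0) comes from the package's own fitting oracle
(`fit_spurious_model`): drawing unrelated kmer pairs conditioned on
RY-space equality makes each base mismatch independently with probability
exactly 1/2 (two nucleotides per RY class), independent of k; the
least-squares power-law fit converges there and the Monte-Carlo fit is
tested against that closed form. Both coefficients are configuration
(`--spurious-a/-b`), not constants, since realistic contaminant panels
give flatter, k-dependent mismatch spectra.

## Indexing

Minimizers are selected by winnowing: all kmers of a window of w
consecutive start positions and their reverse complements are hashed with
Thomas Wang's unseeded 64-bit mix, and the smallest-hash canonical kmer is
kept (leftmost on window ties; forward orientation on palindromic hash
ties — both tie-breaks are arbitrary but fixed for determinism). Kmers with
ambiguous bases never compete. Circular sequences are indexed with a
virtual wrap-around extension, windows wrap, and offsets are reported
modulo the length, making the key set rotation-invariant.

The RY index is *not* an independent winnowing of the RY-transformed
panel — that would select a different kmer set and lose completeness.
Instead the minimizer key set itself is projected (the RY class is the low
bit of each 2-bit base code, so projection is bit extraction), and each RY
key's value lists the minimizer keys that produced it, giving O(1)
RY→minimizer recovery. Completeness (every minimizer reachable from its RY
key) is asserted exhaustively in the tests after every build.

At query time a damaged kmer can canonicalize in the opposite orientation
from its undamaged original (damage changes the hash), so rescue probes
both the RY key and its RY reverse complement.

## Alignment stand-ins

Clustering and extension operate purely in nucleotide space and are shared
verbatim between the rescue and baseline paths. Seeds cluster by
(sequence, strand, diagonal ± 5); the top 8 clusters are extended
gaplessly from the cluster's leftmost exact seed (leftmost rescued seed if
none) with match +1, mismatch −4, and an X-drop of 20. The extension trims
back to the running-score maximum only when the X-drop rule actually
fires; a forced stop at the read end keeps the full extension, so terminal
damage mismatches stay aligned — essential for unbiased damage-rate
re-estimation, since deamination concentrates exactly where trimming would
otherwise remove it. Reads whose best score falls below 0.6 × read length
are unmapped; MAPQ is min(60, 2·(best − second best)), 0 on exact ties,
with deterministic (seq_id, ref_start) tie-breaks. Indels are not modeled:
fragments are short and the rescue logic is independent of gap handling.
At most 64 hits are expanded per rescued key to bound repeat blow-up.
These parameters are documented stand-ins for the internals of production
pangenome aligners and are all surfaced as flags.

## Synthetic benchmark conditions

The generator emulates a mitochondrial-style experiment: a random (by
default 10 kb, circular) genome; endogenous fragments with log-normal
lengths (mean-log log 42, sd-log 0.3, truncated to [30, 120] bp — the
short, right-skewed regime typical of Paleolithic cave samples); fragment
starts uniform with wrap-around, strands fair-coin. Damage is applied in
the sequenced-read orientation: each C becomes T with probability
δ(C>T, position), each G becomes A with δ(G>A, position). For symmetric
double-stranded profiles this is distributionally identical to damaging
the forward strand first and then reverse-complementing, and it is the
only frame in which single-stranded patterns show the expected C→T at both
read ends. NuMT-like decoys embed a diverged copy (default 5%) of a random
mitochondrial segment in random host sequence; contaminant reads come from
an unrelated random genome. Base qualities are constant 'I' and no
sequencing-error model is applied by default (an optional uniform
substitution rate exists for robustness testing), matching the filter's
scope.

Parametric damage profiles use exponential end decay
d(i) = d_base + (d_max − d_base)·λ^i with defaults d_base = 0.01, λ = 0.7,
L = 10 rows, and d_max of 0 / 0.15 / 0.2 / 0.5 for the none /
single-stranded / double-stranded-mid / double-stranded-high patterns.
λ = 0.7 keeps appreciable damage out to positions ~8–10, as in published
high-damage profiles; these matrices are synthetic stand-ins with the
canonical shape, not empirical tables. What passing tests on these data do
*not* show: robustness to sequencing error, indels, base-quality
variation, or contaminants with genuine homology spectra.

## Problem sizes and verification

The test suite verifies winnowing against a naive every-window oracle (50
random sequences per (k,w) ∈ {(5,2),(5,4),(10,2),(15,5)}), baseline
byte-identity of rescue-disabled vs impassable-filter runs on 1,000-read
datasets, sensitivity monotonicity on five 3,000-read high-damage
replicates at (15,5), and damage-profile recovery on 10⁴ reads at the
sensitivity-optimized (10,2) with a five-replicate RMSE comparison at the
default (29,11). These sizes were chosen so the full suite completes in
about a minute while leaving binomial error bars small relative to the
effects tested.

One caveat is intrinsic to the stand-in extension: with damage-blind
scoring and the 0.6·length score floor, reads carrying ≥3 deamination
events are unmappable regardless of seed rescue (~2–3% of
double-stranded-high reads). The surviving-read damage estimates are
exactly unbiased for the mapped set, but the selection deficit leaves
per-position rates ~1–1.5 SE below the generating profile, so the
strictest recovery assertion can sit marginally outside 3 binomial SE
depending on the replicate. Rescue consistently reduces (never increases)
this deficit, and the RMSE comparison reflects that on every tested
replicate.
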