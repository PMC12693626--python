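"""Seed-and-extend mapping of reads against an indexed haplotype panel.

Seeding follows the rescue-then-aggregate scheme: the read is winnowed with
the same (w,k) parameters as the panel, exact kmer-space lookups become
ordinary seeds, and kmers absent from the minimizer index are retried in RY
space.  RY hits recover the minimizer keys that produced them; each
recovered key is compared base-by-base against the read kmer, pushed
through the Bayesian filter, and survivors join the seed set as rescued
seeds.  Everything downstream — diagonal clustering, gapless X-drop
extension, mapping quality — operates in ordinary nucleotide space and is
identical with or without rescue, so disabling rescue (or an impassable
filter threshold) reproduces the baseline aligner exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from .damage import DamageProfile
from .encoding import (
    decode_kmer,
    kmer_key_to_rymer_key,
    reverse_complement,
    ry_reverse_complement,
    ry_string,
    KmerKey,
)
from .indexing import (
    FORWARD,
    REVERSE,
    HaplotypePanel,
    Hit,
    IndexError_,
    MinimizerIndex,
    RymerIndex,
    lookup_minimizer,
    lookup_rymer,
    select_minimizers,
)
from .seed_filter import FilterParams, SeedComparison, posterior

__all__ = [
    "Seed",
    "Alignment",
    "MappingResult",
    "AlignerConfig",
    "find_seeds",
    "cluster_seeds",
    "extend_gapless",
    "map_read",
    "map_reads",
    "write_sam",
    "read_fastq",
]


@dataclass
class AlignerConfig:
    """Stand-in heuristics around the rescue logic, all overridable."""

    match: int = 1
    mismatch: int = -4
    xdrop: int = 20
    cluster_tolerance: int = 5  # max diagonal deviation within a cluster
    max_clusters: int = 8  # extend only the top-ranked clusters
    max_rescue_hits: int = 64  # cap hits expanded per RY key
    min_score_fraction: float = 0.6  # unmapped below this fraction of read length
    rescue: bool = True


@dataclass(frozen=True)
class Seed:
    """An anchored read/reference correspondence.

    ``strand`` and ``oriented_offset`` are derived for clustering: the seed
    start within the read as written in reference-forward orientation.
    """

    read_offset: int
    hit: Hit
    key: KmerKey
    rescued: bool
    posterior: float
    strand: int
    oriented_offset: int

    @property
    def diagonal(self) -> int:
        return self.hit.offset - self.oriented_offset


@dataclass
class Alignment:
    read_name: str
    seq_id: int
    ref_start: int  # 0-based, forward reference strand
    strand: int
    aligned_length: int
    score: int
    edits: list[tuple[int, str, str]]  # (offset in alignment, ref base, read base)
    mapq: int = 0
    rescued_seed_used: bool = False
    min_rescue_posterior: float = 1.0
    n_rescued_seeds: int = 0
    clip_left: int = 0  # soft clips, in oriented-read coordinates
    clip_right: int = 0


@dataclass
class MappingResult:
    name: str
    seq: str
    qual: str | None
    alignment: Alignment | None  # None = unmapped


def _check_parameters(min_index: MinimizerIndex, ry_index: RymerIndex) -> None:
    if (min_index.k, min_index.w) != (ry_index.k, ry_index.w):
        raise IndexError_(
            "index parameter mismatch: minimizer (k,w)="
            f"({min_index.k},{min_index.w}) vs RY ({ry_index.k},{ry_index.w})"
        )


def find_seeds(
    read: str,
    min_index: MinimizerIndex,
    ry_index: RymerIndex,
    profile: DamageProfile,
    params: FilterParams | None = None,
    config: AlignerConfig | None = None,
) -> list[Seed]:
    """Window-minimizer seeding with RY-space rescue of missing kmers."""
    _check_parameters(min_index, ry_index)
    params = params or FilterParams()
    config = config or AlignerConfig()
    k = min_index.k
    read = read.upper()
    n = len(read)
    if n < k:
        return []
    try:
        read_minimizers = select_minimizers(read, k, min_index.w, circular=False)
    except IndexError_:
        return []

    seeds: dict[tuple[int, Hit], Seed] = {}

    def add(seed: Seed) -> None:
        ident = (seed.read_offset, seed.hit)
        existing = seeds.get(ident)
        if existing is None or (existing.rescued and not seed.rescued):
            seeds[ident] = seed

    for key, read_hit in read_minimizers:
        read_offset, o_read = read_hit.offset, read_hit.orientation
        exact_hits = lookup_minimizer(min_index, key)
        if exact_hits:
            for hit in exact_hits:
                strand = o_read ^ hit.orientation
                r_off = read_offset if strand == FORWARD else n - read_offset - k
                add(Seed(read_offset, hit, key, False, 1.0, strand, r_off))
            continue
        if not config.rescue:
            continue

        # RY rescue: the damaged kmer may canonicalize in either orientation,
        # so probe the RY key and its RY reverse complement.
        read_sub = read[read_offset : read_offset + k]
        rykey = kmer_key_to_rymer_key(key)
        probes = [(rykey, 0)]
        ry_rc = ry_reverse_complement(rykey)
        if ry_rc != rykey:
            probes.append((ry_rc, 1))
        for probe, flipped in probes:
            for cand_key in lookup_rymer(ry_index, probe):
                eff = o_read ^ flipped
                cand_seq = decode_kmer(cand_key)
                index_kmer = cand_seq if eff == FORWARD else reverse_complement(cand_seq)
                if ry_string(index_kmer) != ry_string(read_sub):
                    continue
                m = sum(a != b for a, b in zip(read_sub, index_kmer))
                if m == 0:
                    continue  # would have been an exact lookup hit
                cmp = SeedComparison(
                    read_kmer=read_sub,
                    index_kmer=index_kmer,
                    m=m,
                    pos5_of_kmer_start=read_offset,
                    read_length=n,
                    orientation=eff,
                )
                post = posterior(cmp, profile, params)
                if post < params.threshold_j:
                    continue
                hits = lookup_minimizer(min_index, cand_key)[: config.max_rescue_hits]
                for hit in hits:
                    strand = eff ^ hit.orientation
                    r_off = read_offset if strand == FORWARD else n - read_offset - k
                    add(Seed(read_offset, hit, cand_key, True, post, strand, r_off))

    return list(seeds.values())


def cluster_seeds(
    seeds: list[Seed], config: AlignerConfig | None = None
) -> list[list[Seed]]:
    """Group seeds by (sequence, strand, diagonal +- tolerance).

    Clusters are ranked by seed count (descending), then leftmost reference
    position, for deterministic extension order.
    """
    config = config or AlignerConfig()
    groups: dict[tuple[int, int], list[Seed]] = {}
    for s in seeds:
        groups.setdefault((s.hit.seq_id, s.strand), []).append(s)
    clusters: list[list[Seed]] = []
    for (_, _), grp in sorted(groups.items()):
        grp.sort(key=lambda s: (s.diagonal, s.oriented_offset))
        current: list[Seed] = []
        for s in grp:
            if current and abs(s.diagonal - current[0].diagonal) > config.cluster_tolerance:
                clusters.append(current)
                current = []
            current.append(s)
        if current:
            clusters.append(current)
    clusters.sort(key=lambda c: (-len(c), min(s.hit.offset for s in c), c[0].hit.seq_id))
    return clusters


def _anchor(cluster: list[Seed]) -> Seed:
    exact = [s for s in cluster if not s.rescued]
    pool = exact if exact else cluster
    return min(pool, key=lambda s: s.oriented_offset)


def extend_gapless(
    read: str,
    ref_seq: str,
    cluster: list[Seed],
    k: int,
    circular: bool = False,
    config: AlignerConfig | None = None,
    read_name: str = "",
) -> Alignment | None:
    """Bidirectional gapless X-drop extension from the cluster's anchor seed.

    Scoring is damage-blind (+1 match / -4 mismatch by default); extension
    halts at read or reference ends or when the running score drops more
    than ``xdrop`` below its running maximum, then trims back to the
    maximum.  The anchor kmer span is always retained.
    """
    if not cluster:
        return None
    config = config or AlignerConfig()
    anchor = _anchor(cluster)
    strand = anchor.strand
    oriented = read.upper() if strand == FORWARD else reverse_complement(read.upper())
    n = len(oriented)
    ref_len = len(ref_seq)
    g0 = anchor.hit.offset - anchor.oriented_offset  # ref position of oriented[0]

    def ref_base(i: int) -> str | None:
        pos = g0 + i
        if circular:
            return ref_seq[pos % ref_len]
        if 0 <= pos < ref_len:
            return ref_seq[pos]
        return None

    def base_score(i: int) -> int | None:
        rb = ref_base(i)
        if rb is None:
            return None
        return config.match if oriented[i] == rb else config.mismatch

    a_start, a_end = anchor.oriented_offset, anchor.oriented_offset + k
    anchor_score = 0
    for i in range(a_start, a_end):
        s = base_score(i)
        if s is None:
            return None  # anchor runs off a linear reference
        anchor_score += s

    # rightward: trim back to the maximum only if the X-drop rule fires; a
    # forced stop at the read (or linear reference) end keeps the full
    # extension, so terminal damage mismatches remain aligned
    running = best = 0
    right_end = last = a_end
    dropped = False
    for i in range(a_end, n):
        s = base_score(i)
        if s is None:
            break
        running += s
        last = i + 1
        if running > best:
            best, right_end = running, i + 1
        elif running < best - config.xdrop:
            dropped = True
            break
    if not dropped:
        right_end, best = last, running
    right_score = best

    # leftward
    running = best = 0
    left_start = last = a_start
    dropped = False
    for i in range(a_start - 1, -1, -1):
        s = base_score(i)
        if s is None:
            break
        running += s
        last = i
        if running > best:
            best, left_start = running, i
        elif running < best - config.xdrop:
            dropped = True
            break
    if not dropped:
        left_start, best = last, running
    left_score = best

    score = anchor_score + left_score + right_score
    edits = []
    for i in range(left_start, right_end):
        rb = ref_base(i)
        if oriented[i] != rb:
            edits.append((i - left_start, rb, oriented[i]))
    ref_start = g0 + left_start
    if circular:
        ref_start %= ref_len
    rescued = [s for s in cluster if s.rescued]
    return Alignment(
        read_name=read_name,
        seq_id=anchor.hit.seq_id,
        ref_start=ref_start,
        strand=strand,
        aligned_length=right_end - left_start,
        score=score,
        edits=edits,
        rescued_seed_used=bool(rescued),
        min_rescue_posterior=min((s.posterior for s in rescued), default=1.0),
        n_rescued_seeds=len(rescued),
        clip_left=left_start,
        clip_right=n - right_end,
    )


def map_read(
    name: str,
    read: str,
    panel: HaplotypePanel,
    min_index: MinimizerIndex,
    ry_index: RymerIndex,
    profile: DamageProfile,
    params: FilterParams | None = None,
    config: AlignerConfig | None = None,
) -> Alignment | None:
    """Map one read: seed, cluster, extend the top clusters, score-rank.

    MAPQ is min(60, 2 * (best - second-best)) and 0 on an exact tie; reads
    whose best score falls below ``min_score_fraction * len(read)`` are
    unmapped.  Ties break deterministically by (seq_id, ref_start).
    """
    config = config or AlignerConfig()
    seeds = find_seeds(read, min_index, ry_index, profile, params, config)
    if not seeds:
        return None
    clusters = cluster_seeds(seeds, config)[: config.max_clusters]
    alignments: list[Alignment] = []
    for cluster in clusters:
        seq_id = cluster[0].hit.seq_id
        aln = extend_gapless(
            read,
            panel.seq(seq_id),
            cluster,
            min_index.k,
            circular=panel.is_circular(seq_id),
            config=config,
            read_name=name,
        )
        if aln is not None:
            alignments.append(aln)
    if not alignments:
        return None
    # identical alignments reached from different clusters are one candidate
    unique: dict[tuple[int, int, int, int], Alignment] = {}
    for aln in alignments:
        ident = (aln.seq_id, aln.strand, aln.ref_start, aln.score)
        prev = unique.get(ident)
        if prev is None:
            unique[ident] = aln
        elif aln.rescued_seed_used and not prev.rescued_seed_used:
            pass  # keep the exact-seeded record
        elif prev.rescued_seed_used and not aln.rescued_seed_used:
            unique[ident] = aln
    ranked = sorted(unique.values(), key=lambda a: (-a.score, a.seq_id, a.ref_start))
    best = ranked[0]
    if best.score < config.min_score_fraction * len(read):
        return None
    if len(ranked) == 1:
        best.mapq = 60
    elif ranked[1].score == best.score:
        best.mapq = 0
    else:
        best.mapq = min(60, 2 * (best.score - ranked[1].score))
    return best


def map_reads(
    reads,
    panel: HaplotypePanel,
    min_index: MinimizerIndex,
    ry_index: RymerIndex,
    profile: DamageProfile,
    params: FilterParams | None = None,
    config: AlignerConfig | None = None,
) -> list[MappingResult]:
    """Map an iterable of (name, seq, qual) records."""
    results = []
    for name, seq, qual in reads:
        aln = map_read(name, seq, panel, min_index, ry_index, profile, params, config)
        results.append(MappingResult(name, seq, qual, aln))
    return results


def read_fastq(path) -> list[tuple[str, str, str | None]]:
    with pysam.FastxFile(str(path)) as fh:
        return [(e.name, e.sequence, e.quality) for e in fh]


def write_sam(results: list[MappingResult], panel: HaplotypePanel, path) -> None:
    """Write mapped and unmapped records as SAM.

    Custom tags: ``ry:i`` number of rescued seeds in the winning cluster,
    ``pj:f`` minimum posterior among them.  The header carries no command
    line or timestamp, so identical mappings serialize byte-identically.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq, _ in panel.sequences],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for res in results:
            a = pysam.AlignedSegment(out.header)
            a.query_name = res.name
            aln = res.alignment
            if aln is None:
                a.is_unmapped = True
                a.query_sequence = res.seq
                a.query_qualities = (
                    pysam.qualitystring_to_array(res.qual) if res.qual else None
                )
                out.write(a)
                continue
            oriented = (
                res.seq.upper()
                if aln.strand == FORWARD
                else reverse_complement(res.seq.upper())
            )
            qual = res.qual
            if qual is not None and aln.strand == REVERSE:
                qual = qual[::-1]
            a.query_sequence = oriented
            if qual is not None:
                a.query_qualities = pysam.qualitystring_to_array(qual)
            a.is_reverse = aln.strand == REVERSE
            a.reference_id = aln.seq_id
            a.reference_start = aln.ref_start
            a.mapping_quality = aln.mapq
            cigar = []
            if aln.clip_left:
                cigar.append((pysam.CSOFT_CLIP, aln.clip_left))
            cigar.append((pysam.CMATCH, aln.aligned_length))
            if aln.clip_right:
                cigar.append((pysam.CSOFT_CLIP, aln.clip_right))
            a.cigartuples = cigar
            a.set_tag("NM", len(aln.edits), "i")
            a.set_tag("AS", aln.score, "i")
            a.set_tag("ry", aln.n_rescued_seeds, "i")
            if aln.rescued_seed_used:
                a.set_tag("pj", float(aln.min_rescue_posterior), "f")
            out.write(a)
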