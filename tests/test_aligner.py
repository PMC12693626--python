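"""Seeding with RY rescue, clustering, gapless extension, and SAM output."""

import numpy as np
import pysam
import pytest

from rymeralign.aligner import (
    AlignerConfig,
    MappingResult,
    Seed,
    cluster_seeds,
    extend_gapless,
    find_seeds,
    map_read,
    map_reads,
    write_sam,
)
from rymeralign.damage import _SUB_INDEX, make_parametric_profile
from rymeralign.encoding import reverse_complement
from rymeralign.indexing import (
    FORWARD,
    HaplotypePanel,
    Hit,
    IndexError_,
    build_indexes,
    build_minimizer_index,
    build_rymer_index,
    select_minimizers,
)
from rymeralign.seed_filter import FilterParams
from conftest import random_seq

K, W = 11, 4


@pytest.fixture
def indexed_panel(small_panel):
    mi, ry = build_indexes(small_panel, K, W)
    return small_panel, mi, ry


def test_exact_read_gives_only_exact_seeds(indexed_panel, zero_profile):
    panel, mi, ry = indexed_panel
    read = panel.seq(0)[500:550]
    seeds = find_seeds(read, mi, ry, zero_profile)
    assert seeds and all(not s.rescued for s in seeds)
    assert all(s.posterior == 1.0 for s in seeds)
    # seeds place the read where it came from
    assert {s.hit.offset - s.read_offset for s in seeds} == {500}


def test_parameter_mismatch_rejected(indexed_panel, zero_profile):
    panel, mi, _ = indexed_panel
    other_ry = build_rymer_index(build_minimizer_index(panel, K, W + 1))
    with pytest.raises(IndexError_, match="parameter mismatch"):
        find_seeds("A" * 40, mi, other_ry, zero_profile)


def _damaged_fixture(rng):
    """A 2k-1-long read whose central base is a deaminated C: every kmer of
    the read overlaps the damaged base, so no exact seed can exist, while
    the RY projection still matches the indexed minimizer at the locus."""
    from rymeralign.encoding import encode_kmer
    from rymeralign.indexing import wang_hash

    def canonical(sub):
        fwd, rev = encode_kmer(sub), encode_kmer(reverse_complement(sub))
        return fwd if wang_hash(fwd.bits) <= wang_hash(rev.bits) else rev

    seq = random_seq(rng, 2000)
    panel = HaplotypePanel([("hap0", seq, False)])
    mi, ry = build_indexes(panel, K, W)
    mid = K - 1  # center of a 2K-1 read
    for start in range(300, 1500):
        read = seq[start : start + 2 * K - 1]
        if read[mid] != "C":
            continue
        damaged = read[:mid] + "T" + read[mid + 1 :]
        probe = select_minimizers(damaged, K, W)
        if not probe:
            continue
        # no damaged kmer may coincidentally be indexed elsewhere
        if any(key in mi.table for key, _ in probe):
            continue
        # at least one selected read minimizer must sit on an indexed
        # reference minimizer so RY rescue has something to recover
        recoverable = False
        for _, h in probe:
            ref_key = canonical(seq[start + h.offset : start + h.offset + K])
            hits = mi.table.get(ref_key, [])
            if any(hit.offset == start + h.offset for hit in hits):
                recoverable = True
        if recoverable:
            return panel, mi, ry, damaged, start
    raise AssertionError("fixture construction failed")


def test_rescue_recovers_damaged_seed_and_threshold_one_disables(rng):
    panel, mi, ry, read, start = _damaged_fixture(rng)
    profile = make_parametric_profile("double_stranded_high")
    params = FilterParams(threshold_j=0.5)
    seeds = find_seeds(read, mi, ry, profile, params)
    rescued = [s for s in seeds if s.rescued]
    assert rescued, "expected at least one rescued seed"
    assert all(0.5 <= s.posterior < 1.0 for s in rescued)
    assert any(s.hit.offset - s.read_offset == start for s in rescued)
    # an impassable threshold reproduces the no-rescue behavior
    assert find_seeds(read, mi, ry, profile, FilterParams(threshold_j=1.0)) == []
    no_rescue = find_seeds(read, mi, ry, profile, params, AlignerConfig(rescue=False))
    assert no_rescue == []


def test_zero_damage_profile_blocks_rescue(rng, zero_profile):
    panel, mi, ry, read, _ = _damaged_fixture(rng)
    assert find_seeds(read, mi, ry, zero_profile, FilterParams(threshold_j=0.5)) == []


def _seed(read_offset, seq_id, offset, strand=FORWARD, rescued=False):
    from rymeralign.encoding import encode_kmer

    return Seed(
        read_offset,
        Hit(seq_id, offset, FORWARD),
        encode_kmer("A" * K),
        rescued,
        1.0,
        strand,
        read_offset,
    )


def test_codiagonal_seeds_cluster_together():
    s1, s2 = _seed(0, 0, 100), _seed(10, 0, 110)
    assert len(cluster_seeds([s1, s2])) == 1


def test_different_sequences_never_merge():
    s1, s2 = _seed(0, 0, 100), _seed(0, 1, 100)
    assert len(cluster_seeds([s1, s2])) == 2


def test_cluster_tolerance_boundary():
    base = _seed(0, 0, 100)
    within = _seed(10, 0, 115)  # diagonal 105, offset +5
    beyond = _seed(10, 0, 116)  # diagonal 106, offset +6
    assert len(cluster_seeds([base, within])) == 1
    assert len(cluster_seeds([base, beyond])) == 2


def test_perfect_read_full_length_score(small_panel, zero_profile):
    mi, ry = build_indexes(small_panel, K, W)
    read = small_panel.seq(0)[700:760]
    aln = map_read("r", read, small_panel, mi, ry, zero_profile)
    assert aln is not None
    assert (aln.ref_start, aln.aligned_length, aln.score) == (700, 60, 60)
    assert aln.edits == [] and aln.mapq == 60


def test_single_mismatch_costs_five(small_panel, zero_profile):
    mi, ry = build_indexes(small_panel, K, W)
    ref = small_panel.seq(0)
    read = list(ref[700:760])
    read[30] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[30]]
    aln = map_read("r", "".join(read), small_panel, mi, ry, zero_profile)
    assert aln.score == 55 and aln.aligned_length == 60
    assert [(p, rb) for p, rb, _ in aln.edits] == [(30, ref[730])]


def test_xdrop_stops_near_junction_of_random_tail(small_panel, zero_profile, rng):
    mi, ry = build_indexes(small_panel, K, W)
    good = small_panel.seq(0)[700:740]
    read = good + random_seq(rng, 40)
    aln = map_read("r", read, small_panel, mi, ry, zero_profile,
                   config=AlignerConfig(min_score_fraction=0.3))
    assert aln is not None
    # oracle: best-scoring prefix interval by exhaustive scan on the diagonal
    ref = small_panel.seq(0)
    scores = [1 if read[i] == ref[700 + i] else -4 for i in range(len(read))]
    best_end = max(range(1, len(read) + 1), key=lambda e: (sum(scores[:e]), -e))
    assert aln.ref_start == 700
    assert abs((aln.clip_left + aln.aligned_length) - best_end) <= 5
    assert aln.score >= sum(scores[:best_end]) - 20


def test_reverse_strand_read_maps_back(small_panel, zero_profile):
    mi, ry = build_indexes(small_panel, K, W)
    read = reverse_complement(small_panel.seq(0)[820:880])
    aln = map_read("r", read, small_panel, mi, ry, zero_profile)
    assert aln is not None and aln.strand == 1
    assert aln.ref_start == 820 and aln.score == 60


def test_two_identical_copies_tie_mapq_zero(rng, zero_profile):
    seq = random_seq(rng, 1000)
    panel = HaplotypePanel([("a", seq, False), ("b", seq, False)])
    mi, ry = build_indexes(panel, K, W)
    aln = map_read("r", seq[100:160], panel, mi, ry, zero_profile)
    assert aln is not None and aln.mapq == 0
    assert aln.seq_id == 0  # deterministic tie-break


def test_unseedable_read_is_unmapped(small_panel, zero_profile):
    mi, ry = build_indexes(small_panel, K, W)
    assert map_read("r", "N" * 50, small_panel, mi, ry, zero_profile) is None
    assert map_read("r", "ACG", small_panel, mi, ry, zero_profile) is None


def test_circular_read_spanning_origin(rng, zero_profile):
    seq = random_seq(rng, 1000)
    panel = HaplotypePanel([("c", seq, True)])
    mi, ry = build_indexes(panel, K, W)
    read = seq[-25:] + seq[:25]
    aln = map_read("r", read, panel, mi, ry, zero_profile)
    assert aln is not None
    assert aln.ref_start == 975 and aln.score == 50


def test_superset_property_on_damaged_sample(zero_profile):
    """Rescue only ever adds mapped reads, and baseline alignments are
    reproduced identically."""
    from rymeralign.simulator import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(n_endogenous=300, n_contaminant=100, genome_length=8000)
    panel, reads, profile = simulate_dataset(cfg, seed=3)
    mi, ry = build_indexes(panel, 15, 5)
    recs = [(r.name, r.sequence, None) for r in reads]
    with_rescue = map_reads(recs, panel, mi, ry, profile, config=AlignerConfig(rescue=True))
    baseline = map_reads(recs, panel, mi, ry, profile, config=AlignerConfig(rescue=False))
    base_map = {r.name: r.alignment for r in baseline if r.alignment}
    resc_map = {r.name: r.alignment for r in with_rescue if r.alignment}
    assert set(base_map) <= set(resc_map)
    for name, aln in base_map.items():
        got = resc_map[name]
        assert (got.seq_id, got.ref_start, got.strand, got.score) == (
            aln.seq_id, aln.ref_start, aln.strand, aln.score,
        )


def test_sam_output_round_trips_through_pysam(tmp_path, small_panel, zero_profile):
    mi, ry = build_indexes(small_panel, K, W)
    reads = [
        ("mapped", small_panel.seq(0)[100:160], "I" * 60),
        ("revmapped", reverse_complement(small_panel.seq(0)[300:350]), "I" * 50),
        ("unmapped", "N" * 40, "I" * 40),
    ]
    results = map_reads(reads, small_panel, mi, ry, zero_profile)
    path = tmp_path / "out.sam"
    write_sam(results, small_panel, path)
    with pysam.AlignmentFile(str(path), "r") as sam:
        assert [(sq["SN"], sq["LN"]) for sq in sam.header["SQ"]] == [
            ("hap0", len(small_panel.seq(0)))
        ]
        recs = list(sam.fetch(until_eof=True))
    by_name = {r.query_name: r for r in recs}
    assert by_name["mapped"].reference_start == 100
    assert by_name["mapped"].cigarstring == "60M"
    assert by_name["mapped"].get_tag("NM") == 0
    assert by_name["mapped"].get_tag("AS") == 60
    assert by_name["mapped"].get_tag("ry") == 0
    assert by_name["revmapped"].is_reverse
    assert by_name["unmapped"].is_unmapped
    assert by_name["unmapped"].reference_id == -1
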