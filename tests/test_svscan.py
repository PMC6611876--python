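"""Partition, rearrangement classification/merging and variant calling,
checked against engineered truth and a string-diff oracle."""

import numpy as np
import pytest

from polysv.align import AlignmentBlock, seed_and_chain, filter_one_to_one, filter_global
from polysv.formats import GenomeSet
from polysv.svscan import (
    SyntenyPartition,
    call_variants,
    classify_rearrangements,
    merge_rearranged,
    partition_allelic,
    RearrangedRegion,
)
from polysv.synth import SvRequest, simulate_genome_pair


def _blk(rs, re_, qs, qe, idy=1.0, orient="+", rc="r1", qc="q1"):
    return AlignmentBlock(rc, rs, re_, qc, qs, qe, orient, idy)


# -- partition ---------------------------------------------------------------


def test_collinear_pair_all_allelic():
    ref, qry, _ = simulate_genome_pair(1, 300_000, snp_rate=0.005, seed=30)
    blocks = seed_and_chain(ref, qry)
    one2one = filter_one_to_one(blocks)
    part = partition_allelic(one2one, filter_global(one2one))
    assert part.nonallelic == []
    assert len(part.allelic) == len(one2one)


def test_empty_chain_everything_nonallelic():
    blocks = [_blk(0, 100, 0, 100), _blk(200, 300, 200, 300)]
    part = partition_allelic(blocks, [])
    assert part.allelic == [] and len(part.nonallelic) == 2


def test_engineered_inversion_blocks_are_nonallelic(sv_bench):
    part = sv_bench["part"]
    truth_inv = [sv for sv in sv_bench["truth"].engineered_svs
                 if sv["kind"] == "inversion"]
    for sv in truth_inv:
        c, (s, e) = sv["ref_chrom"], sv["ref_span"]
        covering = [b for b in part.nonallelic
                    if b.ref_chrom == c and b.ref_start < e and b.ref_end > s]
        covered = sum(min(b.ref_end, e) - max(b.ref_start, s) for b in covering)
        assert covered >= 0.9 * (e - s)


def test_partition_is_a_partition(sv_bench):
    part = sv_bench["part"]
    assert len(part.allelic) + len(part.nonallelic) == len(sv_bench["one2one"])
    assert not (set(map(id, part.allelic)) & set(map(id, part.nonallelic)))


# -- classification ----------------------------------------------------------


def test_six_engineered_events_recovered_with_kind_and_breakpoints(sv_bench):
    k = sv_bench["k"]
    regions = sv_bench["regions"]
    for sv in sv_bench["truth"].engineered_svs:
        c, (s, e) = sv["ref_chrom"], sv["ref_span"]
        hits = [r for r in regions
                if r.kind == sv["kind"] and r.ref_chrom == c
                and abs(r.ref_span[0] - s) <= k and abs(r.ref_span[1] - e) <= k]
        assert hits, f"missed {sv['kind']} {c}:{s}-{e}"


def test_no_spurious_regions_at_5kb_scale(sv_bench):
    truth_spans = [
        (sv["ref_chrom"], *sv["ref_span"])
        for sv in sv_bench["truth"].engineered_svs
    ]
    for r in sv_bench["regions"]:
        if r.ref_span[1] - r.ref_span[0] >= 5000:
            assert any(
                c == r.ref_chrom and r.ref_span[0] < e and r.ref_span[1] > s
                for c, s, e in truth_spans
            ), f"spurious {r.kind} {r.ref_chrom}:{r.ref_span}"


def test_forward_same_chrom_displacement_is_intra_translocation():
    part = SyntenyPartition(
        allelic=[_blk(0, 1000, 0, 1000), _blk(2000, 3000, 2000, 3000)],
        nonallelic=[_blk(1200, 1500, 2400, 2700)],
    )
    (r,) = classify_rearrangements(part)
    assert r.kind == "intra_translocation"


def test_other_chromosome_flanks_give_inter_translocation():
    part = SyntenyPartition(
        allelic=[_blk(0, 1000, 0, 1000), _blk(2000, 3000, 2000, 3000)],
        nonallelic=[_blk(1200, 1500, 500, 800, qc="q2")],
    )
    (r,) = classify_rearrangements(part)
    assert r.kind == "inter_translocation"


def test_orphan_block_flagged_low_confidence():
    part = SyntenyPartition(
        allelic=[_blk(0, 1000, 0, 1000, rc="r2", qc="q2")],
        nonallelic=[_blk(100, 400, 100, 400, orient="-")],
    )
    (r,) = classify_rearrangements(part)
    assert r.low_confidence


# -- merging -----------------------------------------------------------------


def _region(kind, s, e, qs, qe, rc="r1", qc="q1"):
    return RearrangedRegion(kind, rc, (s, e), qc, (qs, qe),
                            [_blk(s, e, qs, qe, rc=rc, qc=qc)])


def test_merge_joins_fragments_within_gap():
    regs = [_region("inversion", 0, 10_000, 0, 10_000),
            _region("inversion", 15_000, 30_000, 15_000, 30_000)]
    merged = merge_rearranged(regs, join_gap=50_000)
    assert len(merged) == 1
    assert merged[0].ref_span == (0, 30_000)
    assert merged[0].total_length == 25_000


def test_merge_zero_gap_is_identity():
    regs = [_region("inversion", 0, 10_000, 0, 10_000),
            _region("inversion", 15_000, 30_000, 15_000, 30_000)]
    assert len(merge_rearranged(regs, join_gap=0)) == 2


def test_merge_never_mixes_kinds():
    regs = [_region("inversion", 0, 10_000, 0, 10_000),
            _region("intra_translocation", 11_000, 20_000, 11_000, 20_000)]
    assert len(merge_rearranged(regs, join_gap=10 ** 6)) == 2


def test_merge_count_monotone_in_join_gap():
    rng = np.random.default_rng(0)
    starts = np.cumsum(rng.integers(5000, 40_000, size=12))
    regs = [_region("inversion", int(s), int(s + 3000), int(s), int(s + 3000))
            for s in starts]
    counts = [len(merge_rearranged(regs, join_gap=g))
              for g in (0, 5000, 20_000, 50_000, 10 ** 6)]
    assert counts == sorted(counts, reverse=True)


# -- variant calling ---------------------------------------------------------


def _pipeline_calls(ref, qry, buffer_min):
    blocks = seed_and_chain(ref, qry)
    one2one = filter_one_to_one(blocks)
    part = partition_allelic(one2one, filter_global(one2one))
    return call_variants(part.allelic, ref, qry, buffer_min=buffer_min)


def test_identical_genomes_no_variants():
    ref, qry, _ = simulate_genome_pair(1, 100_000, seed=31)
    assert _pipeline_calls(ref, qry, 0) == []


def test_single_planted_snp_called_at_true_position():
    ref, qry, truth = simulate_genome_pair(1, 100_000, seed=32)
    s = ref.sequences["c01"]
    alt = "T" if s[50_000] != "T" else "A"
    qry = GenomeSet("q", {"c01": s[:50_000] + alt + s[50_001:]})
    calls = _pipeline_calls(ref, qry, 20)
    assert [(c.kind, c.ref_pos, c.ref_allele, c.alt_allele) for c in calls] == [
        ("snp", 50_000, s[50_000], alt)
    ]


def test_close_snp_pair_suppressed_by_buffer():
    ref, _, _ = simulate_genome_pair(1, 100_000, seed=33)
    s = ref.sequences["c01"]
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    q = list(s)
    q[50_000] = flip[q[50_000]]
    q[50_010] = flip[q[50_010]]
    qry = GenomeSet("q", {"c01": "".join(q)})
    assert _pipeline_calls(ref, qry, 20) == []
    assert len(_pipeline_calls(ref, qry, 0)) == 2


def test_snp_calls_equal_string_diff_oracle():
    """With buffering off and only length-preserving rearrangements, calls
    outside engineered spans must equal the direct character-by-character
    comparison of the two genomes."""
    ref, qry, truth = simulate_genome_pair(
        1, 1_000_000, snp_rate=0.01,
        sv_spec=[SvRequest("inversion", "c01", 300_000, 360_000)], seed=35,
    )
    calls = _pipeline_calls(ref, qry, 0)
    spans = truth.sv_spans("A")

    def outside(chrom, pos):
        return not any(c == chrom and s <= pos < e for c, s, e in spans)

    called = {(c.ref_chrom, c.ref_pos, c.ref_allele, c.alt_allele)
              for c in calls if c.kind == "snp" and outside(c.ref_chrom, c.ref_pos)}
    oracle = set()
    for chrom in ref.sequences:
        a = ref.sequences[chrom]
        b = qry.sequences[chrom]
        diff = np.nonzero(
            np.frombuffer(a.encode(), np.uint8) != np.frombuffer(b.encode(), np.uint8)
        )[0]
        for p in diff:
            if outside(chrom, int(p)):
                oracle.add((chrom, int(p), a[p], b[p]))
    assert called == oracle


def test_buffered_variants_respect_spacing(sv_bench):
    calls = call_variants(sv_bench["part"].allelic, sv_bench["ref"],
                          sv_bench["qry"], buffer_min=20)
    assert calls
    assert all(c.buffer_distance >= 20 for c in calls if c.kind == "snp")
    by_chrom: dict = {}
    for c in calls:
        by_chrom.setdefault(c.ref_chrom, []).append(c.ref_pos)
    for positions in by_chrom.values():
        gaps = np.diff(sorted(positions))
        assert (gaps >= 20).all()


def test_planted_indels_recovered():
    ref, qry, truth = simulate_genome_pair(1, 500_000, snp_rate=0.0,
                                           indel_rate=5e-4, seed=34)
    calls = _pipeline_calls(ref, qry, 0)
    truth_indels = [v for v in truth.planted_variants if v.kind != "snp"]
    called_pos = {(c.kind, c.ref_pos) for c in calls}
    hits = sum(
        any(v.kind == k and abs(v.pos - p) <= 12 for k, p in called_pos)
        for v in truth_indels
    )
    assert hits >= 0.95 * len(truth_indels)


def test_missing_base_alignment_is_hard_error():
    b = _blk(0, 100, 0, 100)
    ref = GenomeSet("r", {"r1": "A" * 100})
    qry = GenomeSet("q", {"q1": "A" * 100})
    with pytest.raises(ValueError, match="lacks a base alignment"):
        call_variants([b], ref, qry)


def test_nonallelic_length_invariant_to_chrom_order(sv_bench):
    ref, qry = sv_bench["ref"], sv_bench["qry"]
    flipped = GenomeSet(ref.assembly_id,
                        dict(reversed(list(ref.sequences.items()))))
    blocks = seed_and_chain(flipped, qry)
    one2one = filter_one_to_one(blocks)
    part = partition_allelic(one2one, filter_global(one2one))
    orig = sum(b.ref_len for b in sv_bench["part"].nonallelic)
    assert sum(b.ref_len for b in part.nonallelic) == orig
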