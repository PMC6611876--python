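"""Shared fixtures: session-scoped synthetic benchmarks reused by the unit
and acceptance tests so the heavy simulations run once."""

import numpy as np
import pytest

from polysv import align, pavscan, svscan
from polysv.synth import (
    PavRequest,
    SvRequest,
    simulate_genome_pair,
    simulate_introgression_trio,
    simulate_panel,
)


def run_sv_pipeline(ref, qry, k=21):
    blocks = align.seed_and_chain(ref, qry, k=k)
    one2one = align.filter_one_to_one(blocks)
    chain = align.filter_global(one2one)
    part = svscan.partition_allelic(one2one, chain)
    regions = svscan.merge_rearranged(svscan.classify_rearrangements(part))
    return dict(blocks=blocks, one2one=one2one, chain=chain, part=part,
                regions=regions)


SV_BENCH_EVENTS = [
    SvRequest("inversion", "c01", 1_000_000, 1_080_000),
    SvRequest("inversion", "c01", 3_000_000, 3_060_000),
    SvRequest("intra_translocation", "c01", 2_000_000, 2_040_000, dest_pos=2_500_000),
    SvRequest("intra_translocation", "c02", 1_500_000, 1_535_000, dest_pos=1_800_000),
    SvRequest("inter_translocation", "c02", 3_000_000, 3_040_000,
              dest_chrom="c01", dest_pos=4_200_000),
    SvRequest("inter_translocation", "c01", 4_500_000, 4_530_000,
              dest_chrom="c02", dest_pos=2_500_000),
]


@pytest.fixture(scope="session")
def sv_bench():
    """Two 2x5-Mb genomes at 1% SNP divergence with six engineered
    rearrangements (two inversions, two intra- and two inter-chromosomal
    translocations), plus the full scan pipeline run on them."""
    ref, qry, truth = simulate_genome_pair(
        n_chrom=2, chrom_len=5_000_000, snp_rate=0.01, indel_rate=0.0,
        sv_spec=SV_BENCH_EVENTS, seed=11,
    )
    out = run_sv_pipeline(ref, qry)
    out.update(ref=ref, qry=qry, truth=truth, k=21)
    return out


@pytest.fixture(scope="session")
def pav_bench():
    """One 1-Mb pair with engineered presence/absence events on both sides."""
    pavs = [
        PavRequest("insertion", "c01", 200_000, length=3000),
        PavRequest("insertion", "c01", 450_000, length=1500),
        PavRequest("deletion", "c01", 650_000, 652_000),
        PavRequest("deletion", "c01", 840_000, 844_000),
    ]
    ref, qry, truth = simulate_genome_pair(
        n_chrom=1, chrom_len=1_000_000, snp_rate=0.005, indel_rate=0.0,
        pav_spec=pavs, seed=7,
    )
    out = run_sv_pipeline(ref, qry)
    out.update(ref=ref, qry=qry, truth=truth)
    out["pav_qry"] = pavscan.filter_pav(
        pavscan.categorize_unaligned(out["part"], qry, side="qry"), qry, ref
    )
    out["pav_ref"] = pavscan.filter_pav(
        pavscan.categorize_unaligned(out["part"], ref, side="ref"), ref, qry
    )
    return out


@pytest.fixture(scope="session")
def intro_trio():
    """Subgenome/ancestor trio with two planted introgression swaps."""
    sub, own, other, truth = simulate_introgression_trio(
        chrom_len=2_000_000, seed=3
    )
    return dict(sub=sub, own=own, other=other, truth=truth)


@pytest.fixture(scope="session")
def default_panel():
    """The default accession panel (66 reference-like + 348 alternate-like)."""
    matrix, truth = simulate_panel(seed=1)
    return dict(matrix=matrix, truth=truth)
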