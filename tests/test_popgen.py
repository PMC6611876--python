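"""Population-genetics statistics against closed forms and independent
per-site oracles."""

import numpy as np
import pandas as pd
import pytest

from polysv.popgen import (
    GenotypeMatrix,
    combine_breakpoint_calls,
    filter_sites,
    fst_per_site,
    fst_windows,
    genotype_breakpoints,
    genotype_distances,
    hapdiv_windows,
    mean_cm_per_bin,
    nj_groups,
    pi_windows,
    private_common_snps,
    recomb_windows,
)
from polysv.synth import simulate_mate_pairs, simulate_ril_map


def _matrix(geno, positions=None, accessions=None, groups=None, chrom="c1"):
    geno = np.asarray(geno, dtype=np.int8)
    n, m = geno.shape
    accessions = accessions or [f"a{i}" for i in range(n)]
    positions = positions if positions is not None else np.arange(m) * 100
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(accessions, sites, geno, groups)


# -- site filtering ----------------------------------------------------------


def test_filter_sites_thresholds():
    # site 0: MAF 0.03 (3% alt)     -> removed
    # site 1: 15% missing           -> removed
    # site 2: 20% heterozygous      -> removed
    # site 3: clean                 -> kept
    n = 100
    g = np.zeros((n, 4), dtype=np.int8)
    g[:3, 0] = 2
    g[:15, 1] = -1
    g[15:65, 1] = 2
    g[:20, 2] = 1
    g[20:70, 2] = 2
    g[:50, 3] = 2
    kept = filter_sites(_matrix(g))
    assert kept.sites["pos"].tolist() == [300]


def test_filter_passing_matrix_unchanged():
    g = np.zeros((10, 3), dtype=np.int8)
    g[:5] = 2
    m = _matrix(g)
    assert filter_sites(m).n_sites == 3


# -- pi ----------------------------------------------------------------------


def test_pi_two_accessions_one_difference_closed_form():
    g = [[0], [2]]
    df = pi_windows(_matrix(g, positions=[500]), window=1_000_000, step=1_000_000)
    assert df["value"].iloc[0] == pytest.approx(1e-6)


def test_pi_monomorphic_zero():
    g = np.full((5, 10), 2, dtype=np.int8)
    df = pi_windows(_matrix(g))
    assert (df["value"] == 0).all()


def test_pi_recovers_simulated_diversity():
    rng = np.random.default_rng(3)
    n_acc, n_sites = 100, 2000
    g = (rng.random((n_acc, n_sites)) < 0.5).astype(np.int8) * 2
    pos = np.sort(rng.choice(1_000_000, n_sites, replace=False))
    df = pi_windows(_matrix(g, positions=pos), window=1_000_000, step=1_000_000)
    expected = n_sites * 0.5 * (n_acc / (n_acc - 1)) / 1e6
    assert df["value"].iloc[0] == pytest.approx(expected, rel=0.1)


# -- F_ST --------------------------------------------------------------------


def _wc_oracle(g1, g2):
    """Independent per-site Weir-Cockerham theta, written as explicit loops
    straight from the variance-component definitions."""
    thetas = []
    for s in range(g1.shape[1]):
        comps = []
        for g in (g1[:, s], g2[:, s]):
            g = g[g >= 0]
            n = len(g)
            p = g.sum() / (2 * n)
            h = (g == 1).sum() / n
            comps.append((n, p, h))
        (n1, p1, h1), (n2, p2, h2) = comps
        r = 2
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        a = nbar / nc * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        thetas.append((a, a + b + c))
    return thetas


def _grouped_matrix(g1, g2):
    g = np.vstack([g1, g2])
    accs = [f"p{i}" for i in range(len(g1))] + [f"q{i}" for i in range(len(g2))]
    groups = {a: ("P" if a.startswith("p") else "Q") for a in accs}
    return _matrix(g, accessions=accs, groups=groups)


def test_fst_equals_per_site_oracle_to_1e10():
    rng = np.random.default_rng(7)
    g1 = rng.choice([0, 1, 2, -1], size=(8, 20), p=[0.4, 0.1, 0.45, 0.05]).astype(np.int8)
    g2 = rng.choice([0, 1, 2, -1], size=(12, 20), p=[0.2, 0.1, 0.65, 0.05]).astype(np.int8)
    m = _grouped_matrix(g1, g2)
    oracle = _wc_oracle(g1, g2)
    num = sum(a for a, _ in oracle)
    den = sum(d for _, d in oracle)
    df = fst_windows(m, window=10_000, step=10_000)
    assert df["value"].iloc[0] == pytest.approx(num / den, abs=1e-10)
    per_site = fst_per_site(m)
    for theta, (a, d) in zip(per_site, oracle):
        if d != 0:
            assert theta == pytest.approx(a / d, abs=1e-10)


def test_fst_fixed_difference_is_one():
    g1 = np.zeros((10, 5), dtype=np.int8)
    g2 = np.full((10, 5), 2, dtype=np.int8)
    df = fst_windows(_grouped_matrix(g1, g2), window=10_000, step=10_000)
    assert df["value"].iloc[0] == pytest.approx(1.0)


def test_fst_identical_frequencies_near_zero():
    rng = np.random.default_rng(8)
    base = (rng.random((60, 200)) < 0.4).astype(np.int8) * 2
    df = fst_windows(_grouped_matrix(base[:30], base[30:]),
                     window=100_000, step=100_000)
    assert abs(df["value"].iloc[0]) < 0.02


def test_fst_requires_two_groups():
    g = np.zeros((4, 3), dtype=np.int8)
    m = _matrix(g, groups={f"a{i}": "G" for i in range(4)})
    with pytest.raises(ValueError, match="two groups"):
        fst_windows(m)


# -- haplotype diversity -----------------------------------------------------


def test_hapdiv_all_identical_zero():
    g = np.tile(np.array([0, 2, 0, 2], dtype=np.int8), (6, 1))
    df = hapdiv_windows(_matrix(g), cluster_window=10_000,
                        avg_window=10_000, step=10_000)
    assert df["value"].iloc[0] == pytest.approx(0.0)


def test_hapdiv_all_distinct_closed_form():
    g = np.array([[0, 0], [0, 2], [2, 0], [2, 2]], dtype=np.int8)
    df = hapdiv_windows(_matrix(g), cluster_window=10_000,
                        avg_window=10_000, step=10_000)
    assert df["value"].iloc[0] == pytest.approx((4 / 3) * (1 - 4 * (1 / 16)))


def test_hapdiv_missing_is_own_cluster():
    g = np.array([[0, 0], [0, 0], [0, -1]], dtype=np.int8)
    df = hapdiv_windows(_matrix(g), cluster_window=10_000,
                        avg_window=10_000, step=10_000)
    # clusters {a0,a1} and {a2}: (3/2)(1 - (4/9 + 1/9))
    assert df["value"].iloc[0] == pytest.approx(1.5 * (1 - 5 / 9))


def test_hapdiv_invariant_to_orderings():
    rng = np.random.default_rng(5)
    g = rng.choice([0, 2], size=(12, 8)).astype(np.int8)
    m = _matrix(g)
    base = hapdiv_windows(m, 10_000, 10_000, 10_000)["value"].iloc[0]
    perm = rng.permutation(12)
    m2 = GenotypeMatrix([m.accessions[i] for i in perm], m.sites, g[perm])
    assert hapdiv_windows(m2, 10_000, 10_000, 10_000)["value"].iloc[0] == \
        pytest.approx(base)
    sperm = rng.permutation(8)
    m3 = _matrix(g[:, sperm], positions=np.arange(8) * 100)
    assert hapdiv_windows(m3, 10_000, 10_000, 10_000)["value"].iloc[0] == \
        pytest.approx(base)


def test_hapdiv_reduced_inside_inversion(default_panel):
    m = filter_sites(default_panel["matrix"])
    _, s, e = default_panel["truth"].inversion_span
    ref_accs = [a for a, g in default_panel["truth"].inversion_alleles.items()
                if g == "ref_like"]
    df = hapdiv_windows(m, accessions=ref_accs)
    inside = df[(df["start"] >= s) & (df["end"] <= e)]["value"].mean()
    outside = df[(df["end"] <= s) | (df["start"] >= e)]["value"].mean()
    assert inside < outside


# -- private / common SNPs ---------------------------------------------------


def test_private_common_partition():
    g1 = np.array([[2, 2, 0, 0], [2, 0, 0, 0]], dtype=np.int8)
    g2 = np.array([[2, 0, 2, 0], [0, 0, 2, 0]], dtype=np.int8)
    m = _grouped_matrix(g1, g2)
    counts = private_common_snps(m, seed=0)
    assert counts["common"] == 1  # site 0 segregates in both
    assert counts["private_P"] == 1  # site 1 only in P
    assert counts["private_Q"] == 1  # site 2 only in Q
    segregating = counts["common"] + counts["private_P"] + counts["private_Q"]
    assert segregating == 3  # site 3 is monomorphic reference


def test_private_common_downsamples_larger_group():
    rng = np.random.default_rng(11)
    g1 = (rng.random((5, 50)) < 0.3).astype(np.int8) * 2
    g2 = (rng.random((40, 50)) < 0.3).astype(np.int8) * 2
    counts = private_common_snps(_grouped_matrix(g1, g2), seed=1)
    assert counts["n_downsampled"] == 5


# -- neighbour joining -------------------------------------------------------


def test_nj_three_taxon_additive_solution():
    # pairwise differences (AB, AC, BC) = (2, 3, 3) over 10 sites; the unique
    # additive solution is a=(2+3-3)/2=1, b=(2+3-3)/2=1, c=(3+3-2)/2=2 diffs,
    # i.e. tip branches 0.1, 0.1, 0.2 after dividing by the site count
    g = np.array(
        [
            [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
            [2, 2, 0, 0, 0, 0, 0, 0, 0, 0],
            [2, 0, 0, 2, 2, 0, 0, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    m = _matrix(g, accessions=["A", "B", "C"])
    d = genotype_distances(m)
    assert (d[0, 1], d[0, 2], d[1, 2]) == (0.2, 0.3, 0.3)
    newick, _ = nj_groups(m)
    import re

    lengths = {
        name: float(ln)
        for name, ln in re.findall(r"([ABC]):([\d.eE+-]+)", newick)
    }
    assert lengths["A"] == pytest.approx(0.1, abs=1e-9)
    assert lengths["B"] == pytest.approx(0.1, abs=1e-9)
    assert lengths["C"] == pytest.approx(0.2, abs=1e-9)


def test_nj_two_cut_separates_identical_groups():
    g = np.vstack([np.zeros((4, 10), np.int8), np.full((5, 10), 2, np.int8)])
    g[:, 0] = [0, 0, 0, 0, 2, 2, 2, 2, 2]
    m = _matrix(g)
    _, cut = nj_groups(m)
    left = {a for a, c in cut.items() if c == cut["a0"]}
    assert left == {"a0", "a1", "a2", "a3"}


def test_nj_concordant_with_inversion_truth(default_panel):
    m = filter_sites(default_panel["matrix"])
    _, cut = nj_groups(m)
    truth = default_panel["truth"].inversion_alleles
    sides = {}
    for acc, cluster in cut.items():
        sides.setdefault(truth[acc], set()).add(cluster)
    assert all(len(s) == 1 for s in sides.values())
    assert sides["ref_like"] != sides["alt_like"]


# -- breakpoint genotyping ---------------------------------------------------


BPS = [("SV1_L", "c08", 12_000_000), ("SV1_R", "c08", 20_000_000)]


def test_unanimous_concordant_pairs_give_ref_like():
    pairs = simulate_mate_pairs("c08", 30_000_000, (12_000_000, 20_000_000),
                                "ref", n_pairs=10, seed=1, accession="x")
    calls = genotype_breakpoints(pairs, BPS, 3000, 300)
    assert all(c.allele == "ref_like" for c in calls)


def test_single_pair_below_support_floor_unassigned():
    pairs = simulate_mate_pairs("c08", 30_000_000, (12_000_000, 20_000_000),
                                "ref", n_pairs=10, seed=2, accession="x")
    one = pairs.iloc[[0]]
    calls = genotype_breakpoints(one, BPS, 3000, 300, min_support=2)
    assert {c.allele for c in calls} == {"unassigned"}


def test_breakpoint_off_reference_is_error():
    pairs = simulate_mate_pairs("c08", 30_000_000, (12_000_000, 20_000_000),
                                "ref", n_pairs=2, seed=3)
    with pytest.raises(ValueError, match="not on"):
        genotype_breakpoints(pairs, [("bad", "c09", 5)], 3000, 300,
                             chrom_lengths={"c08": 30_000_000})


def test_panel_genotyping_matches_truth_no_contradictions():
    import pandas as pd

    frames, truth_alleles = [], {}
    for i in range(12):
        hap = "ref" if i < 6 else "alt"
        acc = f"acc{i:02d}"
        truth_alleles[acc] = hap
        frames.append(
            simulate_mate_pairs("c08", 30_000_000, (12_000_000, 20_000_000),
                                hap, n_pairs=10, seed=100 + i, accession=acc)
        )
    calls = genotype_breakpoints(pd.concat(frames), BPS, 3000, 300)
    expect = {"ref": "ref_like", "alt": "alt_like"}
    correct = sum(c.allele == expect[truth_alleles[c.accession]] for c in calls)
    assert correct >= 0.95 * len(calls)
    assert not any(  # never the opposite allele
        c.allele not in ("unassigned", expect[truth_alleles[c.accession]])
        for c in calls
    )
    combined = combine_breakpoint_calls(calls)
    assert (combined["combined"] != "unassigned").all()


# -- recombination windows ---------------------------------------------------


def test_uniform_map_every_window_at_baseline():
    gm = simulate_ril_map(10_000_000, 101, baseline_rate=1.0)
    win, _ = recomb_windows(gm)
    interior = win[win["end"] <= 10_000_000]
    assert np.allclose(interior["value"], 1.0)


def test_mean_cm_per_bin_from_totals():
    assert mean_cm_per_bin(3370.91, 4482) == pytest.approx(0.75, abs=0.005)
    gm = simulate_ril_map(10_000_000, 100, baseline_rate=1.0)
    _, mcb = recomb_windows(gm)
    assert mcb == pytest.approx(10.0 / 100, rel=1e-6)


def test_suppressed_span_detected():
    gm = simulate_ril_map(10_000_000, 200, baseline_rate=1.0,
                          suppressed_span=(3_000_000, 6_000_000),
                          suppression_factor=0.1)
    win, _ = recomb_windows(gm)
    inside = win[(win["start"] >= 3_000_000) & (win["end"] <= 6_000_000)]
    outside = win[win["end"] <= 3_000_000]
    assert inside["value"].mean() < 0.2 * outside["value"].mean()


def test_non_monotone_map_is_error():
    gm = pd.DataFrame({"chrom": "c1", "pos": [0, 100, 200], "cm": [0, 1.0, 0.5]})
    with pytest.raises(ValueError, match="non-monotone"):
        recomb_windows(gm)


# -- VCF round trip ----------------------------------------------------------


def test_genotype_matrix_vcf_roundtrip(tmp_path):
    rng = np.random.default_rng(2)
    g = rng.choice([0, 1, 2, -1], size=(5, 30)).astype(np.int8)
    m = _matrix(g, positions=np.sort(rng.choice(10_000, 30, replace=False)))
    p = tmp_path / "panel.vcf"
    m.to_vcf(p)
    from polysv.formats import lint_vcf

    assert lint_vcf(p) == []
    back = GenotypeMatrix.from_vcf(p)
    assert back.accessions == m.accessions
    np.testing.assert_array_equal(back.genotypes, m.genotypes)
    assert back.sites["pos"].tolist() == m.sites["pos"].tolist()
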