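"""Gene-pair effect annotation against a construction oracle: every mutation
class is planted explicitly and the expected label derived independently by
translating the constructed coding sequences."""

import numpy as np
import pytest
from Bio.Seq import Seq

from polysv._dna import random_dna
from polysv.formats import GeneModel, GenomeSet
from polysv.orthostruct import (
    classify_pair,
    compare_gene_pair,
    effect_counts,
    format_percent,
    tabulate,
)
from polysv.synth import embed_gene

FLIP = {"A": "C", "C": "G", "G": "T", "T": "A"}


@pytest.fixture(scope="module")
def locus():
    rng = np.random.default_rng(77)
    seqs = {"c1": random_dna(rng, 12_000)}
    model = embed_gene(seqs, "c1", 5000, "gA", rng,
                       exon_lens=[240, 300, 240], intron_lens=[150, 200])
    return GenomeSet("A", seqs), model


def _pair(locus, b_seq, b_model=None):
    genome_a, model_a = locus
    model_b = b_model or GeneModel("gB", "c1", "+", model_a.exons, model_a.cds)
    return compare_gene_pair(model_a, genome_a, model_b,
                             GenomeSet("B", {"c1": b_seq}))


def _del_iv(iv, s, ln):
    a, b = iv
    return (a - ln if a >= s else a, b - ln if b >= s + ln else b)


def _delete(seq, model, s, ln, drop_exon=None):
    new_seq = seq[:s] + seq[s + ln:]
    exons = [e for i, e in enumerate(model.exons) if i != drop_exon]
    cds = [c for i, c in enumerate(model.cds) if i != drop_exon]
    exons = [_del_iv(e, s, ln) for e in exons]
    cds = [_del_iv(c, s, ln) for c in cds]
    return new_seq, GeneModel("gB", "c1", "+", exons, cds)


def test_identical_pair_no_genic_variation(locus):
    genome_a, _ = locus
    call = _pair(locus, genome_a.sequences["c1"])
    assert "no_genic_variation" in call.effects
    assert call.category == "structurally_conserved"


def test_upstream_only_substitution_distinguishes_genic_rows(locus):
    genome_a, model_a = locus
    seq = genome_a.sequences["c1"]
    p = model_a.span[0] - 1000
    call = _pair(locus, seq[:p] + FLIP[seq[p]] + seq[p + 1:])
    assert "no_cds_intron_variation" in call.effects
    assert "no_genic_variation" not in call.effects
    assert call.category == "structurally_conserved"


def test_start_codon_mutation(locus):
    genome_a, model_a = locus
    seq = genome_a.sequences["c1"]
    p = model_a.cds[0][0] + 2  # ATG -> ATx
    call = _pair(locus, seq[:p] + "A" + seq[p + 1:])
    assert "start_codon" in call.effects
    assert call.category == "large_effect"


def test_splice_donor_mutation(locus):
    genome_a, model_a = locus
    seq = genome_a.sequences["c1"]
    p = model_a.introns[0][0] + 1  # GT -> GC
    call = _pair(locus, seq[:p] + "C" + seq[p + 1:])
    assert "splice_donor" in call.effects
    assert call.category == "large_effect"


def test_splice_acceptor_mutation(locus):
    genome_a, model_a = locus
    seq = genome_a.sequences["c1"]
    p = model_a.introns[1][1] - 2  # AG -> CG
    call = _pair(locus, seq[:p] + "C" + seq[p + 1:])
    assert "splice_acceptor" in call.effects
    assert call.category == "large_effect"


def test_exon_loss_is_large_structural(locus):
    genome_a, model_a = locus
    seq = genome_a.sequences["c1"]
    (s, e) = model_a.exons[1]
    b_seq, b_model = _delete(seq, model_a, s, e - s, drop_exon=1)
    call = _pair(locus, b_seq, b_model)
    assert "exon_count_change" in call.effects
    assert "cds_missing" in call.effects
    assert call.category == "large_structural_variation"


def test_classification_precedence():
    assert classify_pair({"missense"}) == "structurally_conserved"
    assert classify_pair({"inframe_indel", "missense"}) == "structurally_conserved"
    assert classify_pair({"frameshift_indel", "missense"}) == "large_effect"
    assert classify_pair({"cds_missing", "frameshift_indel"}) == \
        "large_structural_variation"
    assert classify_pair(set()) == "structurally_conserved"


def test_internal_stop_in_reference_excluded(locus):
    genome_a, model_a = locus
    seq = genome_a.sequences["c1"]
    s0 = model_a.cds[0][0]
    broken = seq[:s0 + 9] + "TAA" + seq[s0 + 12:]
    call = compare_gene_pair(
        model_a, GenomeSet("A", {"c1": broken}),
        GeneModel("gB", "c1", "+", model_a.exons, model_a.cds),
        GenomeSet("B", {"c1": broken}),
    )
    assert call.flagged == "internal_stop_in_reference"


def test_random_mutations_agree_with_translation_oracle(locus):
    """300 random single mutations; labels must match what direct translation
    of the constructed coding sequences implies."""
    genome_a, model_a = locus
    seq = genome_a.sequences["c1"]
    spliced_a = model_a.spliced_cds(genome_a)
    prot_a = str(Seq(spliced_a).translate())
    rng = np.random.default_rng(123)
    cds_positions = [p for a, b in model_a.cds for p in range(a, b)]
    checked = {"snp": 0, "inframe": 0, "frameshift": 0}
    for _ in range(300):
        kind = rng.choice(["snp", "inframe", "frameshift"])
        if kind == "snp":
            p = int(rng.choice(cds_positions[3:]))
            b_seq = seq[:p] + FLIP[seq[p]] + seq[p + 1:]
            call = _pair(locus, b_seq)
            model_b = GeneModel("gB", "c1", "+", model_a.exons, model_a.cds)
            spliced_b = model_b.spliced_cds(GenomeSet("B", {"c1": b_seq}))
            prot_b = str(Seq(spliced_b).translate())
            if "*" in prot_b[:-1] or not prot_b.endswith("*"):
                expect = "stop_codon"
                assert expect in call.effects
                assert call.category == "large_effect"
            elif prot_b == prot_a:
                assert "same_sense" in call.effects
                assert call.category == "structurally_conserved"
            else:
                assert "missense" in call.effects
                assert call.category == "structurally_conserved"
        else:
            ln = int(rng.choice([3, 6] if kind == "inframe" else [1, 2, 4]))
            a, b = model_a.cds[1]
            s = int(rng.integers(a + 3, b - ln - 3))
            b_seq, b_model = _delete(seq, model_a, s, ln)
            call = _pair(locus, b_seq, b_model)
            spliced_b = b_model.spliced_cds(GenomeSet("B", {"c1": b_seq}))
            prot_b = str(Seq(spliced_b[:len(spliced_b) // 3 * 3]).translate())
            if kind == "inframe":
                assert "inframe_indel" in call.effects
                premature = "*" in prot_b[:-1]
                if premature:
                    assert call.category == "large_effect"
                else:
                    assert call.category == "structurally_conserved"
            else:
                assert "frameshift_indel" in call.effects
                assert call.category == "large_effect"
        checked[kind] += 1
    assert all(v > 30 for v in checked.values())


# -- tabulation --------------------------------------------------------------


def test_percent_formatting_matches_reported_precision():
    assert format_percent(27428, 34243) == "80.10%"
    assert format_percent(4630, 34243) == "13.52%"
    assert format_percent(1, 1) == "100.00%"
    assert format_percent(0, 0) == "0.00%"


def test_tabulate_categories_partition_total(locus):
    genome_a, model_a = locus
    seq = genome_a.sequences["c1"]
    calls = [_pair(locus, seq)]  # conserved
    p = model_a.cds[0][0] + 2
    calls.append(_pair(locus, seq[:p] + "A" + seq[p + 1:]))  # start codon
    (s, e) = model_a.exons[1]
    b_seq, b_model = _delete(seq, model_a, s, e - s, drop_exon=1)
    calls.append(_pair(locus, b_seq, b_model))  # large structural
    df = tabulate(calls)
    top = df[df["row"].isin(
        ["Structurally conserved genes", "Genes with large-effect mutations",
         "Genes with large structural variations"]
    )]
    total = int(df[df["row"] == "Total"]["syntenic_At"].iloc[0])
    assert top["syntenic_At"].sum() == total == 3
    assert df[df["row"] == "Total"]["syntenic_At_pct"].iloc[0] == "100.00%"
    flat = effect_counts(calls)
    assert set(flat["effect"]) >= {"start_codon", "exon_count_change"}
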