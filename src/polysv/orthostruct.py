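"""Classification of orthologous gene pairs into a structural-variation
taxonomy: structurally conserved, large-effect mutation, or large structural
variation.

For each pair the genic region plus 2 kb of flank is aligned base-by-base,
variants are assigned to sub-regions (flank / UTR / CDS / intron), both
coding sequences are translated, and the pair receives a set of effect
labels from which the category follows by precedence:
large-structural (exon count change or a missing CDS segment) beats
large-effect (frameshift, start/stop codon, splice site) beats conserved
(at most synonymous/missense substitutions and in-frame indels).
Ortholog pairing itself is an input (truth pairing or a user list), not
something inferred here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from ._dna import revcomp
from .align import align_ops
from .formats import GeneModel, GenomeSet

log = logging.getLogger("polysv")

LARGE_SV_EFFECTS = {"exon_count_change", "cds_missing"}
LARGE_EFFECTS = {
    "frameshift_indel", "start_codon", "stop_codon", "splice_donor",
    "splice_acceptor",
}
REGIONS = ("upstream", "downstream", "utr", "cds", "intron")


@dataclass
class OrthoPairCall:
    gene_a: str
    gene_b: str
    syntenic: bool
    subgenome: str
    effects: set[str] = field(default_factory=set)
    category: str = "structurally_conserved"
    flagged: str | None = None  # unalignable / internal-stop / non-canonical


@dataclass
class _Locus:
    seq: str
    gene_span: tuple[int, int]  # local coordinates, coding strand
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    truncated: bool


def _localize(model: GeneModel, genome: GenomeSet, flank: int) -> _Locus:
    """Extract the genic region plus flanks on the coding strand, with model
    intervals mapped into local coordinates."""
    chrom_len = genome.lengths[model.chromosome]
    s, e = model.span
    ws, we = max(0, s - flank), min(chrom_len, e + flank)
    truncated = ws != s - flank or we != e + flank
    seq = genome.fetch(model.chromosome, ws, we)

    def to_local(iv):
        a, b = iv
        if model.strand == "+":
            return a - ws, b - ws
        return we - b, we - a

    if model.strand == "-":
        seq = revcomp(seq)
    exons = sorted(to_local(iv) for iv in model.exons)
    cds = sorted(to_local(iv) for iv in model.cds)
    return _Locus(seq, to_local((s, e)), exons, cds, truncated)


def _region_of(pos: int, locus: _Locus) -> str:
    gs, ge = locus.gene_span
    if pos < gs:
        return "upstream"
    if pos >= ge:
        return "downstream"
    for a, b in locus.cds:
        if a <= pos < b:
            return "cds"
    for a, b in locus.exons:
        if a <= pos < b:
            return "utr"
    return "intron"


def align_gene_pair(model_a: GeneModel, genome_a: GenomeSet,
                    model_b: GeneModel, genome_b: GenomeSet,
                    flank: int = 2000) -> dict:
    """Globally align the two genic regions (plus flanks) and collect
    variants per sub-region of gene A.

    Returns a dict with ``variants`` (list of (a_pos, kind, length, region)),
    the two localized loci, and per-CDS-segment gap fractions used for the
    missing-CDS test.
    """
    la = _localize(model_a, genome_a, flank)
    lb = _localize(model_b, genome_b, flank)
    ops = align_ops(lb.seq, la.seq)  # query = gene B, target = gene A
    variants = []
    gap_in_b = [0] * len(la.cds)  # columns of each A CDS segment deleted in B
    apos = bpos = 0
    for op, n in ops:
        if op == "=":
            apos += n
            bpos += n
        elif op == "X":
            for i in range(n):
                variants.append((apos + i, "snp", 1, _region_of(apos + i, la)))
            apos += n
            bpos += n
        elif op == "I":  # present only in B
            variants.append((apos, "insertion", n, _region_of(apos, la)))
            bpos += n
        else:  # 'D': present only in A, absent from B
            variants.append((apos, "deletion", n, _region_of(apos, la)))
            for i, (a, b) in enumerate(la.cds):
                gap_in_b[i] += max(0, min(b, apos + n) - max(a, apos))
            apos += n
    return dict(
        variants=variants, locus_a=la, locus_b=lb, gap_in_b=gap_in_b,
        truncated=la.truncated or lb.truncated,
    )


def _splice_sites(locus: _Locus):
    """(donor GT-like, acceptor AG-like) dinucleotides per intron."""
    sites = []
    for (_, b), (c, _) in zip(locus.exons, locus.exons[1:]):
        sites.append((locus.seq[b : b + 2], locus.seq[c - 2 : c]))
    return sites


def _spliced(locus: _Locus) -> str:
    return "".join(locus.seq[a:b] for a, b in locus.cds)


def annotate_effects(alignment: dict, model_a: GeneModel,
                     model_b: GeneModel,
                     missing_cds_frac: float = 0.8) -> tuple[set[str], str | None]:
    """Derive the effect label set from an aligned pair.

    Returns ``(effects, flag)``; a non-None flag marks pairs to exclude from
    tabulation (reference gene with an internal stop, unalignable input).
    """
    la, lb = alignment["locus_a"], alignment["locus_b"]
    cds_a, cds_b = _spliced(la), _spliced(lb)
    if len(cds_a) < 3:
        return set(), "unalignable"
    prot_a = str(Seq(cds_a[: len(cds_a) - len(cds_a) % 3]).translate())
    prot_b = str(Seq(cds_b[: len(cds_b) - len(cds_b) % 3]).translate())
    if "*" in prot_a[:-1]:
        return set(), "internal_stop_in_reference"

    effects: set[str] = set()
    variants = alignment["variants"]
    by_region: dict[str, list] = {r: [] for r in REGIONS}
    for v in variants:
        by_region[v[3]].append(v)

    if not variants:
        effects.add("no_genic_variation")
    if not by_region["cds"] and not by_region["intron"]:
        effects.add("no_cds_intron_variation")
    if not by_region["cds"]:
        effects.add("no_cds_variation")

    # frame judgement uses the net CDS length difference: the optimal base
    # alignment may split one biological indel into adjacent gap pieces
    indel_net = sum(
        n if kind == "insertion" else -n
        for _, kind, n, _ in by_region["cds"]
        if kind != "snp"
    )
    if any(kind != "snp" for _, kind, _, _ in by_region["cds"]):
        if indel_net % 3 == 0:
            effects.add("inframe_indel")
        else:
            effects.add("frameshift_indel")

    if len(model_a.exons) != len(model_b.exons):
        effects.add("exon_count_change")
    for i, (a, b) in enumerate(la.cds):
        if (b - a) and alignment["gap_in_b"][i] / (b - a) >= missing_cds_frac:
            effects.add("cds_missing")

    if cds_a[:3] == "ATG" and cds_b[:3] != "ATG":
        effects.add("start_codon")
    # stop lost or premature stop gained
    a_stops = prot_a.endswith("*")
    b_stops = prot_b.endswith("*")
    premature_b = "*" in prot_b[:-1]
    if (a_stops and not b_stops and "frameshift_indel" not in effects) or premature_b:
        effects.add("stop_codon")

    if len(model_a.exons) == len(model_b.exons):
        for (da, aa), (db, ab) in zip(_splice_sites(la), _splice_sites(lb)):
            if da == "GT" and db != "GT":
                effects.add("splice_donor")
            if aa == "AG" and ab != "AG":
                effects.add("splice_acceptor")
            if da != "GT" or aa != "AG":
                effects.add("noncanonical_intron")

    # protein-level substitution labels (only meaningful without indels)
    if cds_a != cds_b and by_region["cds"]:
        snps_only = all(v[1] == "snp" for v in by_region["cds"])
        if snps_only and prot_a == prot_b:
            effects.add("same_sense")
        elif snps_only and len(prot_a) == len(prot_b) and prot_a != prot_b:
            if not premature_b:
                effects.add("missense")
    return effects, None


def classify_pair(effects: set[str]) -> str:
    """Category by precedence: structural > large-effect > conserved."""
    if effects & LARGE_SV_EFFECTS:
        return "large_structural_variation"
    if effects & LARGE_EFFECTS:
        return "large_effect"
    return "structurally_conserved"


def compare_gene_pair(model_a: GeneModel, genome_a: GenomeSet,
                      model_b: GeneModel, genome_b: GenomeSet,
                      flank: int = 2000, syntenic: bool = True,
                      subgenome: str = "At") -> OrthoPairCall:
    """Full per-pair pipeline: align, annotate, classify."""
    call = OrthoPairCall(model_a.gene_id, model_b.gene_id, syntenic, subgenome)
    alignment = align_gene_pair(model_a, genome_a, model_b, genome_b, flank)
    effects, flag = annotate_effects(alignment, model_a, model_b)
    call.effects = effects
    call.flagged = flag
    if flag is None:
        call.category = classify_pair(effects)
    return call


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------


def format_percent(count: int, total: int) -> str:
    """Percent of a column total, printed to two decimals (e.g. '80.10%')."""
    if total == 0:
        return "0.00%"
    return f"{100.0 * count / total:.2f}%"


_ROWS = [
    ("Structurally conserved genes", 0,
     lambda c: c.category == "structurally_conserved"),
    ("Without amino acid substitutions", 1,
     lambda c: c.category == "structurally_conserved"
     and not c.effects & {"missense", "inframe_indel"}),
    ("No DNA variation in CDS region", 2,
     lambda c: c.category == "structurally_conserved"
     and "no_cds_variation" in c.effects),
    ("No DNA variation in CDS and intron region", 2,
     lambda c: c.category == "structurally_conserved"
     and "no_cds_intron_variation" in c.effects),
    ("No DNA variation in genic region", 2,
     lambda c: c.category == "structurally_conserved"
     and "no_genic_variation" in c.effects),
    ("Same sense mutation", 2,
     lambda c: c.category == "structurally_conserved"
     and "same_sense" in c.effects),
    ("With amino acid changes", 1,
     lambda c: c.category == "structurally_conserved"
     and bool(c.effects & {"missense", "inframe_indel"})),
    ("With missense mutation in CDS", 2,
     lambda c: c.category == "structurally_conserved"
     and "missense" in c.effects),
    ("With 3n InDel in CDS", 2,
     lambda c: c.category == "structurally_conserved"
     and "inframe_indel" in c.effects),
    ("Genes with large-effect mutations", 0,
     lambda c: c.category == "large_effect"),
    ("With 3n +/- 1 InDel in CDS", 1,
     lambda c: c.category == "large_effect" and "frameshift_indel" in c.effects),
    ("Start-codon mutation", 1,
     lambda c: c.category == "large_effect" and "start_codon" in c.effects),
    ("Stop-codon mutation", 1,
     lambda c: c.category == "large_effect" and "stop_codon" in c.effects),
    ("Splice-acceptor mutation", 1,
     lambda c: c.category == "large_effect" and "splice_acceptor" in c.effects),
    ("Splice-donor mutation", 1,
     lambda c: c.category == "large_effect" and "splice_donor" in c.effects),
    ("Genes with large structural variations", 0,
     lambda c: c.category == "large_structural_variation"),
    ("At least one CDS missing", 1,
     lambda c: c.category == "large_structural_variation"
     and "cds_missing" in c.effects),
]


def tabulate(calls: list[OrthoPairCall]) -> pd.DataFrame:
    """Nested count/percent report by (syntenic x subgenome) column.

    Percentages are of the column total (classified, unflagged pairs),
    printed to two decimals.  A flat per-effect view is available from
    :func:`effect_counts`.
    """
    calls = [c for c in calls if c.flagged is None]
    columns = sorted(
        {(c.syntenic, c.subgenome) for c in calls},
        key=lambda t: (not t[0], t[1]),
    )
    records = []
    for label, depth, pred in _ROWS + [("Total", 0, lambda c: True)]:
        rec = {"row": ("  " * depth) + label}
        for syntenic, sub in columns:
            col = [c for c in calls if c.syntenic == syntenic and c.subgenome == sub]
            n = sum(pred(c) for c in col)
            key = f"{'syntenic' if syntenic else 'nonsyntenic'}_{sub}"
            rec[key] = n
            rec[key + "_pct"] = format_percent(n, len(col))
        records.append(rec)
    return pd.DataFrame(records)


def effect_counts(calls: list[OrthoPairCall]) -> pd.DataFrame:
    """Flat view: how many pairs carry each effect label."""
    calls = [c for c in calls if c.flagged is None]
    labels = sorted({e for c in calls for e in c.effects})
    return pd.DataFrame(
        [
            {"effect": e, "count": sum(e in c.effects for c in calls),
             "percent": format_percent(sum(e in c.effects for c in calls),
                                       len(calls))}
            for e in labels
        ]
    )
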