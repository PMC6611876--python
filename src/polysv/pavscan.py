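"""Presence/absence variation calling from the unaligned complement of a
whole-genome comparison, with show-diff-style categories and the
coverage/identity uniqueness filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .align import ReferenceIndex, seed_and_chain
from .formats import AlignmentBlock, GeneModel, GenomeSet
from .svscan import SyntenyPartition

log = logging.getLogger("polysv")

CATEGORIES = ("GAP", "DUP", "BRK", "JMP", "INV", "SEQ")


@dataclass
class PavRegion:
    """An unaligned region of the carrier genome.

    Categories follow the show-diff vocabulary: GAP (gap between two mutually
    consistent alignments), DUP (inserted duplication), BRK (other inserted
    sequence), JMP (rearrangement), INV (rearrangement with inversion), SEQ
    (rearrangement with another sequence).  ``retained`` is decided by the
    uniqueness filter: a region is not unique when its sequence aligns to the
    counterpart genome with coverage > 50% and identity > 90%.
    """

    carrier: str
    chromosome: str
    start: int
    end: int
    category: str
    counterpart_coverage: float = 0.0
    counterpart_identity: float = 0.0
    retained: bool | None = None
    flagged: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def _carrier_span(b: AlignmentBlock, side: str) -> tuple[str, int, int]:
    if side == "qry":
        return b.qry_chrom, b.qry_start, b.qry_end
    return b.ref_chrom, b.ref_start, b.ref_end


def _counterpart_span(b: AlignmentBlock, side: str) -> tuple[str, int, int]:
    return _carrier_span(b, "ref" if side == "qry" else "qry")


def categorize_unaligned(partition: SyntenyPartition, carrier: GenomeSet,
                         side: str = "qry", min_len: int = 100,
                         ) -> list[PavRegion]:
    """Label the unaligned complement of the carrier genome.

    ``side`` names which side of the comparison the carrier genome is
    (``"qry"`` for the query assembly, ``"ref"`` for the reference).  Regions
    of at most ``min_len`` bp are dropped, per the working definition of a
    PAV as a fragment longer than 100 bp.
    """
    if side not in ("ref", "qry"):
        raise ValueError("side must be 'ref' or 'qry'")
    allelic_ids = {id(b) for b in partition.allelic}
    by_chrom: dict[str, list[AlignmentBlock]] = {c: [] for c in carrier.sequences}
    for b in partition.all_blocks:
        chrom, _, _ = _carrier_span(b, side)
        if chrom in by_chrom:
            by_chrom[chrom].append(b)
    regions: list[PavRegion] = []
    for chrom, blocks in by_chrom.items():
        blocks.sort(key=lambda b: _carrier_span(b, side)[1:])
        length = carrier.lengths[chrom]
        cursor = 0
        left: AlignmentBlock | None = None
        gaps: list[tuple[int, int, AlignmentBlock | None, AlignmentBlock | None]] = []
        for b in blocks:
            _, s, e = _carrier_span(b, side)
            if s > cursor:
                gaps.append((cursor, s, left, b))
            if e > cursor:
                cursor = e
                left = b
        if cursor < length:
            gaps.append((cursor, length, left, None))
        for s, e, bl, br in gaps:
            if e - s <= min_len:
                continue
            category = _categorize_gap(bl, br, allelic_ids, side)
            regions.append(PavRegion(carrier.assembly_id, chrom, s, e, category))
    # carrier-only gap runs inside blocks (events shorter than the chaining
    # gap limit are absorbed into a block instead of splitting it); these sit
    # between two mutually consistent alignment stretches, hence GAP
    for b in partition.all_blocks:
        if b.ops is None:
            continue
        want = "I" if side == "qry" else "D"
        rpos, qpos = b.ref_start, 0
        for op, n in b.ops:
            if op == want and n > min_len:
                if side == "ref":
                    s, e = rpos, rpos + n
                    chrom = b.ref_chrom
                else:
                    chrom = b.qry_chrom
                    if b.orientation == "+":
                        s, e = b.qry_start + qpos, b.qry_start + qpos + n
                    else:
                        s, e = b.qry_end - qpos - n, b.qry_end - qpos
                if chrom in carrier.sequences:
                    regions.append(
                        PavRegion(carrier.assembly_id, chrom, s, e, "GAP")
                    )
            if op in "=XD":
                rpos += n
            if op in "=XI":
                qpos += n
    regions.sort(key=lambda r: (r.chromosome, r.start))
    return regions


def _categorize_gap(bl, br, allelic_ids, side) -> str:
    if bl is None or br is None:
        return "BRK"
    flanks = [bl, br]
    nonallelic = [b for b in flanks if id(b) not in allelic_ids]
    if not nonallelic:
        # two allelic flanks: mutually consistent -> GAP, counterpart
        # re-use (negative counterpart gap) -> inserted duplication
        lc, _, le = _counterpart_span(bl, side)
        rc, rs, _ = _counterpart_span(br, side)
        if lc == rc and bl.orientation == br.orientation:
            cgap = rs - le if bl.orientation == "+" else \
                _counterpart_span(bl, side)[1] - _counterpart_span(br, side)[2]
            # tolerate the few-bp counterpart overlap that maximal anchors
            # can produce at an insertion junction
            return "GAP" if cgap >= -50 else "DUP"
        return "JMP"
    if any(b.orientation == "-" for b in nonallelic):
        return "INV"
    lc = _counterpart_span(bl, side)[0]
    rc = _counterpart_span(br, side)[0]
    if lc != rc:
        return "SEQ"
    return "JMP"


def filter_pav(regions: list[PavRegion], carrier: GenomeSet,
               counterpart: GenomeSet, min_cov: float = 0.5,
               min_ident: float = 0.9, k: int = 21,
               index: ReferenceIndex | None = None) -> list[PavRegion]:
    """Decide uniqueness of each region against the counterpart genome.

    Each region's sequence is aligned to the counterpart with the anchor
    aligner; a region whose best alignment covers more than ``min_cov`` of
    its length at better than ``min_ident`` identity is marked
    ``retained=False`` (present in both genomes, hence not a PAV).
    All-N regions cannot be assessed and are dropped with a flag.
    """
    idx = index if index is not None else ReferenceIndex(counterpart, k)
    out: list[PavRegion] = []
    for r in regions:
        seq = carrier.fetch(r.chromosome, r.start, r.end)
        if set(seq) <= {"N"}:
            r.retained, r.flagged = False, True
            out.append(r)
            continue
        probe = GenomeSet("_pav_probe", {"probe": seq})
        blocks = seed_and_chain(
            counterpart, probe, k=k, min_block=min(100, max(len(seq) // 4, 30)),
            index=idx,
        )
        covered: list[tuple[int, int]] = []
        ident_w = 0.0
        for b in blocks:
            covered.append((b.qry_start, b.qry_end))
            ident_w += b.identity * b.qry_len
        cov_bp = _union_len(covered)
        r.counterpart_coverage = cov_bp / len(seq)
        r.counterpart_identity = (
            ident_w / sum(e - s for s, e in covered) if covered else 0.0
        )
        r.retained = not (
            r.counterpart_coverage > min_cov and r.counterpart_identity > min_ident
        )
        out.append(r)
    return out


def _union_len(intervals: list[tuple[int, int]]) -> int:
    total = 0
    end = -1
    for s, e in sorted(intervals):
        s = max(s, end)
        if e > s:
            total += e - s
            end = e
        end = max(end, e)
    return total


def pav_genes(pavs: list[PavRegion], genes: list[GeneModel],
              min_cds_frac: float = 0.8) -> list[str]:
    """Gene ids whose CDS lies at least ``min_cds_frac`` within retained PAVs."""
    trees: dict[str, IntervalTree] = {}
    for r in pavs:
        if r.retained:
            trees.setdefault(r.chromosome, IntervalTree()).addi(r.start, r.end)
    hits = []
    for g in genes:
        tree = trees.get(g.chromosome)
        if tree is None:
            continue
        inside = 0
        for a, b in g.cds:
            for iv in tree.overlap(a, b):
                inside += min(iv.end, b) - max(iv.begin, a)
        if g.cds_length and inside / g.cds_length >= min_cds_frac:
            hits.append(g.gene_id)
    return hits


def pav_table(pavs: list[PavRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(carrier=r.carrier, chrom=r.chromosome, start=r.start, end=r.end,
                 length=r.length, category=r.category,
                 coverage=round(r.counterpart_coverage, 4),
                 identity=round(r.counterpart_identity, 4),
                 retained=r.retained)
            for r in pavs
        ]
    )


def pav_summary(pavs: list[PavRegion]) -> pd.DataFrame:
    """Per-chromosome count and total length of retained PAVs."""
    df = pav_table([r for r in pavs if r.retained])
    if df.empty:
        return pd.DataFrame(columns=["chrom", "count", "total_bp"])
    return df.groupby("chrom", as_index=False).agg(
        count=("chrom", "size"), total_bp=("length", "sum")
    )
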