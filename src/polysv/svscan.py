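"""Allelic/non-allelic partition of one-to-one alignment blocks, inversion and
translocation classification with region merging, and SNP/InDel calling.

The logic follows the classic two-filter recipe: one-to-one blocks (allowing
rearrangement) minus the global collinear chain define the non-allelic
regions; each non-allelic block is then typed by where and in which
orientation it sits relative to its flanking allelic context, and
neighbouring blocks of the same type are merged into rearranged regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from ._dna import revcomp
from .formats import AlignmentBlock, GenomeSet

log = logging.getLogger("polysv")


@dataclass
class SyntenyPartition:
    allelic: list[AlignmentBlock]
    nonallelic: list[AlignmentBlock]

    @property
    def all_blocks(self) -> list[AlignmentBlock]:
        return sorted(
            self.allelic + self.nonallelic,
            key=lambda b: (b.ref_chrom, b.ref_start),
        )


@dataclass
class RearrangedRegion:
    kind: str  # inversion | intra_translocation | inter_translocation
    ref_chrom: str
    ref_span: tuple[int, int]
    qry_chrom: str
    qry_span: tuple[int, int]
    member_blocks: list[AlignmentBlock] = field(default_factory=list)
    low_confidence: bool = False

    @property
    def total_length(self) -> int:
        return sum(b.ref_len for b in self.member_blocks)


@dataclass
class VariantCall:
    """A called SNP or short indel, VCF-style (indels anchored on the
    preceding reference base)."""

    kind: str  # snp | insertion | deletion
    ref_chrom: str
    ref_pos: int
    ref_allele: str
    alt_allele: str
    length: int = 1
    buffer_distance: int = 0


# ---------------------------------------------------------------------------
# partition
# ---------------------------------------------------------------------------


def _coverage(span: tuple[int, int], intervals: list[tuple[int, int]]) -> float:
    s, e = span
    covered = 0
    for a, b in intervals:
        covered += max(0, min(b, e) - max(a, s))
    return covered / (e - s)


def partition_allelic(one2one: list[AlignmentBlock],
                      global_chain: list[AlignmentBlock],
                      min_chain_cover: float = 0.5) -> SyntenyPartition:
    """Split one-to-one blocks into allelic and non-allelic sets.

    A block is allelic iff at least ``min_chain_cover`` of its reference span
    is covered by the global collinear chain and its orientation matches the
    chain (which is uniformly forward); everything else is non-allelic.
    """
    chain_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in global_chain:
        chain_by_chrom.setdefault(b.ref_chrom, []).append((b.ref_start, b.ref_end))
    allelic, nonallelic = [], []
    for b in one2one:
        cover = _coverage(
            (b.ref_start, b.ref_end), chain_by_chrom.get(b.ref_chrom, [])
        )
        if b.orientation == "+" and cover >= min_chain_cover:
            allelic.append(b)
        else:
            nonallelic.append(b)
    return SyntenyPartition(allelic, nonallelic)


# ---------------------------------------------------------------------------
# rearrangement classification and merging
# ---------------------------------------------------------------------------


def classify_rearrangements(partition: SyntenyPartition) -> list[RearrangedRegion]:
    """Type each non-allelic block from its flanking allelic context.

    inter-chromosomal placement beats orientation: a block whose query
    chromosome differs from where its allelic flanks map is an
    inter_translocation; a reverse-orientation block in the right chromosome
    context is an inversion; a forward block in the right chromosome but with
    order-inconsistent placement is an intra_translocation.  Blocks without
    an allelic neighbour on either side fall back to the chromosome-level
    majority context and are flagged low-confidence.
    """
    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for b in partition.allelic:
        by_chrom.setdefault(b.ref_chrom, []).append(b)
    for blocks in by_chrom.values():
        blocks.sort(key=lambda b: b.ref_start)
    majority: dict[str, str] = {}
    for chrom, blocks in by_chrom.items():
        weight: dict[str, int] = {}
        for b in blocks:
            weight[b.qry_chrom] = weight.get(b.qry_chrom, 0) + b.ref_len
        majority[chrom] = max(weight, key=weight.get)
    # fall back to the genome-wide dominant pairing when a reference
    # chromosome has no allelic blocks at all
    global_weight: dict[str, int] = {}
    for b in partition.allelic:
        global_weight[b.qry_chrom] = global_weight.get(b.qry_chrom, 0) + b.ref_len

    regions = []
    for b in partition.nonallelic:
        flanks = []
        low_conf = False
        neighbours = by_chrom.get(b.ref_chrom, [])
        left = max(
            (a for a in neighbours if a.ref_start <= b.ref_start),
            key=lambda a: a.ref_end, default=None,
        )
        right = min(
            (a for a in neighbours if a.ref_end >= b.ref_end),
            key=lambda a: a.ref_start, default=None,
        )
        flanks = [a for a in (left, right) if a is not None]
        if flanks:
            context = max(
                (a.qry_chrom for a in flanks),
                key=lambda c: sum(x.ref_len for x in flanks if x.qry_chrom == c),
            )
        elif b.ref_chrom in majority:
            context = majority[b.ref_chrom]
            low_conf = True
        else:
            context = max(global_weight, key=global_weight.get) if global_weight else b.qry_chrom
            low_conf = True
        if b.qry_chrom != context:
            kind = "inter_translocation"
        elif b.orientation == "-":
            kind = "inversion"
        else:
            kind = "intra_translocation"
        regions.append(
            RearrangedRegion(
                kind, b.ref_chrom, (b.ref_start, b.ref_end), b.qry_chrom,
                (b.qry_start, b.qry_end), [b], low_conf,
            )
        )
    regions.sort(key=lambda r: (r.ref_chrom, r.ref_span))
    return regions


def merge_rearranged(regions: list[RearrangedRegion],
                     join_gap: int = 50_000) -> list[RearrangedRegion]:
    """Union neighbouring regions of the same kind on the same chromosome
    pair whose reference and query gaps are both at most ``join_gap``.
    The region count is monotonically non-increasing in ``join_gap``."""
    groups: dict[tuple, list[RearrangedRegion]] = {}
    for r in regions:
        groups.setdefault((r.kind, r.ref_chrom, r.qry_chrom), []).append(r)
    merged: list[RearrangedRegion] = []
    for group in groups.values():
        group.sort(key=lambda r: r.ref_span)
        cur = group[0]
        for nxt in group[1:]:
            rgap = nxt.ref_span[0] - cur.ref_span[1]
            qgap = max(
                nxt.qry_span[0] - cur.qry_span[1],
                cur.qry_span[0] - nxt.qry_span[1],
            )
            if rgap <= join_gap and qgap <= join_gap:
                cur = RearrangedRegion(
                    cur.kind, cur.ref_chrom,
                    (cur.ref_span[0], max(cur.ref_span[1], nxt.ref_span[1])),
                    cur.qry_chrom,
                    (min(cur.qry_span[0], nxt.qry_span[0]),
                     max(cur.qry_span[1], nxt.qry_span[1])),
                    cur.member_blocks + nxt.member_blocks,
                    cur.low_confidence or nxt.low_confidence,
                )
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    merged.sort(key=lambda r: (r.ref_chrom, r.ref_span))
    return merged


# ---------------------------------------------------------------------------
# SNP / InDel calling
# ---------------------------------------------------------------------------


def call_variants(allelic_blocks: list[AlignmentBlock], ref: GenomeSet,
                  qry: GenomeSet, buffer_min: int = 20,
                  max_indel: int = 100) -> list[VariantCall]:
    """Read SNPs and short indels off the base alignments of allelic blocks.

    SNPs and single-base indels come from alignment columns and are retained
    only when their distance to the nearest other variant and to the block
    edge is at least ``buffer_min``.  Indels of 2..``max_indel`` bp come from
    within-block gap runs and from length differences of the inter-block gaps
    between mutually consistent adjacent allelic blocks (longer events are
    presence/absence scale and left to the PAV caller).
    """
    events: list[tuple[VariantCall, int, int, bool]] = []  # call, foot start/end, buffered?
    for b in allelic_blocks:
        if b.ops is None:
            raise ValueError(
                f"block {b.ref_chrom}:{b.ref_start}-{b.ref_end} lacks a base alignment"
            )
        oriented = qry.fetch(b.qry_chrom, b.qry_start, b.qry_end)
        if b.orientation == "-":
            oriented = revcomp(oriented)
        rpos, qpos = b.ref_start, 0
        for op, n in b.ops:
            if op == "=":
                rpos += n
                qpos += n
            elif op == "X":
                for i in range(n):
                    call = VariantCall(
                        "snp", b.ref_chrom, rpos + i,
                        ref.fetch(b.ref_chrom, rpos + i, rpos + i + 1),
                        oriented[qpos + i],
                    )
                    events.append((call, rpos + i, rpos + i + 1, True))
                rpos += n
                qpos += n
            elif op == "I":
                anchor = rpos - 1
                call = VariantCall(
                    "insertion", b.ref_chrom, anchor,
                    ref.fetch(b.ref_chrom, anchor, anchor + 1),
                    ref.fetch(b.ref_chrom, anchor, anchor + 1)
                    + oriented[qpos : qpos + n],
                    length=n,
                )
                events.append((call, rpos, rpos, n == 1))
                qpos += n
            elif op == "D":
                anchor = rpos - 1
                call = VariantCall(
                    "deletion", b.ref_chrom, anchor,
                    ref.fetch(b.ref_chrom, anchor, rpos + n),
                    ref.fetch(b.ref_chrom, anchor, anchor + 1),
                    length=n,
                )
                events.append((call, rpos, rpos + n, n == 1))
                rpos += n

    # inter-block GAP-type indels between mutually consistent neighbours
    ordered = sorted(allelic_blocks, key=lambda b: (b.ref_chrom, b.ref_start))
    for b1, b2 in zip(ordered, ordered[1:]):
        if (b1.ref_chrom != b2.ref_chrom or b1.qry_chrom != b2.qry_chrom
                or b1.orientation != "+" or b2.orientation != "+"):
            continue
        rgap = b2.ref_start - b1.ref_end
        qgap = b2.qry_start - b1.qry_end
        if rgap < 0 or qgap < 0:
            continue
        diff = qgap - rgap
        if not 2 <= abs(diff) <= max_indel:
            continue
        anchor = b1.ref_end - 1
        ref_al = ref.fetch(b1.ref_chrom, anchor, b2.ref_start)
        alt_al = (ref.fetch(b1.ref_chrom, anchor, anchor + 1)
                  + qry.fetch(b1.qry_chrom, b1.qry_end, b2.qry_start))
        kind = "insertion" if diff > 0 else "deletion"
        call = VariantCall(kind, b1.ref_chrom, anchor, ref_al, alt_al,
                           length=abs(diff))
        events.append((call, b1.ref_end, b2.ref_start, False))

    # block-edge distances for the buffering rule
    edges: dict[str, list[int]] = {}
    for b in allelic_blocks:
        edges.setdefault(b.ref_chrom, []).extend((b.ref_start, b.ref_end))

    events.sort(key=lambda t: (t[0].ref_chrom, t[1], t[2]))
    out: list[VariantCall] = []
    for i, (call, fs, fe, buffered) in enumerate(events):
        dist = None
        for j in (i - 1, i + 1):
            if 0 <= j < len(events) and events[j][0].ref_chrom == call.ref_chrom:
                gap = max(events[j][1] - fe, fs - events[j][2])
                dist = gap if dist is None else min(dist, gap)
        for edge in edges.get(call.ref_chrom, []):
            gap = min(abs(edge - fs), abs(edge - fe))
            dist = gap if dist is None else min(dist, gap)
        call.buffer_distance = dist if dist is not None else 10 ** 9
        if call.length > max_indel:
            continue
        if buffered and call.buffer_distance < buffer_min:
            continue
        out.append(call)
    out.sort(key=lambda c: (c.ref_chrom, c.ref_pos))
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def region_table(regions: list[RearrangedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                kind=r.kind, ref_chrom=r.ref_chrom, ref_start=r.ref_span[0],
                ref_end=r.ref_span[1], qry_chrom=r.qry_chrom,
                qry_start=r.qry_span[0], qry_end=r.qry_span[1],
                length=r.total_length, n_blocks=len(r.member_blocks),
                confidence="low" if r.low_confidence else "high",
            )
            for r in regions
        ]
    )


def rearrangement_summary(regions: list[RearrangedRegion]) -> pd.DataFrame:
    """Per-kind counts and total megabases, mirroring a per-genome SV table."""
    df = region_table(regions)
    if df.empty:
        return pd.DataFrame(columns=["kind", "count", "total_mb"])
    g = df.groupby("kind", as_index=False).agg(
        count=("kind", "size"), total_bp=("length", "sum")
    )
    g["total_mb"] = g.pop("total_bp") / 1e6
    return g
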