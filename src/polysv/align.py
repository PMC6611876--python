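"""Minimal whole-genome aligner: unique-seed anchoring, collinear chaining,
base-level gap closing, and the two block filters the SV pipeline needs.

The anchoring strategy requires each seed k-mer to occur exactly once in the
reference, which suppresses repeat-induced noise without a repeat masker;
output is interchangeable with imported show-coords/PAF tables, so a real
aligner can substitute for desk-scale work.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import edlib
import numpy as np

from ._dna import encode, kmer_codes, revcomp
from .formats import AlignmentBlock, GenomeSet

log = logging.getLogger("polysv")

DEFAULT_K = 21


@dataclass
class Anchor:
    """A maximal exact unique-in-reference match (reverse matches are stored
    in reverse-complemented-query coordinates while chaining)."""

    ref_chrom: str
    ref_pos: int
    qry_chrom: str
    qry_pos: int
    length: int
    orientation: str


# ---------------------------------------------------------------------------
# base-level alignment helpers
# ---------------------------------------------------------------------------


def align_ops(query: str, target: str) -> list[tuple[str, int]]:
    """Globally align two sequences, returning (op, length) runs.

    Ops: '=' match, 'X' mismatch, 'I' base present only in the query,
    'D' base present only in the target.
    """
    if not query and not target:
        return []
    if not query:
        return [("D", len(target))]
    if not target:
        return [("I", len(query))]
    cigar = edlib.align(query, target, mode="NW", task="path")["cigar"]
    ops: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            op = ch  # edlib extended cigar: I consumes query, D consumes target
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + n)
            else:
                ops.append((op, n))
    return ops


def ops_identity(ops: list[tuple[str, int]]) -> float:
    total = sum(n for _, n in ops)
    if total == 0:
        return 1.0
    return sum(n for op, n in ops if op == "=") / total


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


class ReferenceIndex:
    """Sorted table of the k-mers that occur exactly once in a reference."""

    def __init__(self, ref: GenomeSet, k: int = DEFAULT_K):
        if not 15 <= k <= 31:
            raise ValueError("k must lie in [15, 31]")
        self.ref = ref
        self.k = k
        self.chrom_names = list(ref.sequences)
        codes_parts, pos_parts = [], []
        self.offsets = [0]
        for name in self.chrom_names:
            seq = ref.sequences[name]
            if len(seq) < k:
                log.warning("reference %s shorter than k=%d; no seeds", name, k)
            p, c = kmer_codes(encode(seq), k)
            codes_parts.append(c)
            pos_parts.append(p + self.offsets[-1])
            self.offsets.append(self.offsets[-1] + len(seq))
        codes = np.concatenate(codes_parts) if codes_parts else np.empty(0, np.uint64)
        gpos = np.concatenate(pos_parts) if pos_parts else np.empty(0, np.int64)
        order = np.argsort(codes, kind="stable")
        codes, gpos = codes[order], gpos[order]
        # keep k-mers whose code occurs exactly once
        if len(codes):
            new = np.empty(len(codes), dtype=bool)
            new[0] = True
            np.not_equal(codes[1:], codes[:-1], out=new[1:])
            starts = np.nonzero(new)[0]
            runlen = np.diff(np.append(starts, len(codes)))
            uniq = starts[runlen == 1]
            self.codes = codes[uniq]
            self.gpos = gpos[uniq]
        else:
            self.codes = codes
            self.gpos = gpos

    def lookup(self, qcodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (query-index mask positions, reference global positions)."""
        if len(self.codes) == 0 or len(qcodes) == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        idx = np.searchsorted(self.codes, qcodes)
        idx[idx == len(self.codes)] = 0
        hit = self.codes[idx] == qcodes
        return np.nonzero(hit)[0], self.gpos[idx[hit]]

    def split_global(self, gpos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Global position -> (chromosome index, local position)."""
        ci = np.searchsorted(self.offsets, gpos, side="right") - 1
        local = gpos - np.asarray(self.offsets)[ci]
        return ci, local


def _collapse_runs(qpos: np.ndarray, rpos: np.ndarray, rchrom: np.ndarray,
                   k: int) -> list[tuple[int, int, int, int]]:
    """Merge k-mer matches on a shared diagonal into maximal exact anchors.

    Returns (rchrom_index, rpos, qpos, length) tuples.
    """
    if len(qpos) == 0:
        return []
    diag = rpos - qpos
    order = np.lexsort((qpos, diag, rchrom))
    q, r, d, c = qpos[order], rpos[order], diag[order], rchrom[order]
    brk = np.ones(len(q), dtype=bool)
    brk[1:] = (c[1:] != c[:-1]) | (d[1:] != d[:-1]) | (q[1:] != q[:-1] + 1)
    starts = np.nonzero(brk)[0]
    ends = np.append(starts[1:], len(q))
    return [
        (int(c[s]), int(r[s]), int(q[s]), int(q[e - 1] - q[s] + k))
        for s, e in zip(starts, ends)
    ]


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


class _Chain:
    __slots__ = ("anchors", "r_end", "q_end")

    def __init__(self, anchor):
        self.anchors = [anchor]
        _, r, q, ln = anchor
        self.r_end = r + ln
        self.q_end = q + ln


def _chain_anchors(anchors: list[tuple[int, int, int, int]],
                   max_gap: int) -> list[list[tuple[int, int, int, int]]]:
    """Greedy diagonal-proximity chaining of (c, r, q, len) anchors that share
    a chromosome pair and orientation (coordinates ascending on both sides).
    """
    anchors = sorted(anchors, key=lambda a: (a[1], a[2]))
    active: list[_Chain] = []
    done: list[_Chain] = []
    for a in anchors:
        c, r, q, ln = a
        # retire chains too far behind to ever connect
        still = []
        for ch in active:
            if r - ch.r_end > max_gap:
                done.append(ch)
            else:
                still.append(ch)
        active = still
        best = None
        best_gap = None
        for ch in active:
            rr, qq, lln = r, q, ln
            over = max(ch.r_end - rr, ch.q_end - qq)
            if over > 0:
                rr, qq, lln = rr + over, qq + over, lln - over
                if lln <= 0:
                    continue
            rgap, qgap = rr - ch.r_end, qq - ch.q_end
            if rgap < 0 or qgap < 0 or rgap > max_gap or qgap > max_gap:
                continue
            gap = rgap + qgap
            if best_gap is None or gap < best_gap:
                best, best_gap = ch, gap
                best_anchor = (c, rr, qq, lln)
        if best is None:
            active.append(_Chain(a))
        else:
            best.anchors.append(best_anchor)
            best.r_end = best_anchor[1] + best_anchor[3]
            best.q_end = best_anchor[2] + best_anchor[3]
    done.extend(active)
    return [ch.anchors for ch in done]


def _chain_to_block(chain, ref_seq: str, qry_oriented: str, ref_chrom: str,
                    qry_chrom: str, orientation: str, qry_len: int) -> AlignmentBlock:
    ops: list[tuple[str, int]] = []

    def push(op, n):
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    _, r0, q0, _ = chain[0]
    prev_r, prev_q = r0, q0
    for _, r, q, ln in chain:
        rgap, qgap = r - prev_r, q - prev_q
        if rgap or qgap:
            if rgap == 0:
                push("I", qgap)
            elif qgap == 0:
                push("D", rgap)
            else:
                for op, n in align_ops(qry_oriented[prev_q:q], ref_seq[prev_r:r]):
                    push(op, n)
        push("=", ln)
        prev_r, prev_q = r + ln, q + ln
    if orientation == "+":
        qs, qe = q0, prev_q
    else:  # chain coordinates are on the reverse-complemented query
        qs, qe = qry_len - prev_q, qry_len - q0
    return AlignmentBlock(
        ref_chrom, r0, prev_r, qry_chrom, qs, qe, orientation,
        ops_identity(ops), ops,
    )


def seed_and_chain(ref: GenomeSet, qry: GenomeSet, k: int = DEFAULT_K,
                   max_anchor_gap: int = 2000, min_block: int = 500,
                   min_identity: float = 0.0, min_anchor: int | None = None,
                   index: ReferenceIndex | None = None) -> list[AlignmentBlock]:
    """Align two genomes into base-resolved collinear blocks.

    Anchors are unique-in-reference exact k-mer matches (both strands)
    extended to maximal length, chained greedily when the gap on both genomes
    is at most ``max_anchor_gap`` with consistent orientation; inter-anchor
    gaps are closed by global base-level alignment.  Chains shorter than
    ``min_block`` on either genome, or below ``min_identity``, are dropped.

    ``min_anchor`` (default: k) discards maximal exact matches shorter than
    the given length before chaining; raising it towards ~50 bp emulates a
    large-word-size local search and stops chains from crawling across
    highly diverged sequence.
    """
    idx = index if index is not None and index.k == k else ReferenceIndex(ref, k)
    blocks: list[AlignmentBlock] = []
    for qname, qseq in qry.sequences.items():
        if len(qseq) < k:
            log.warning("query %s shorter than k=%d; skipped", qname, k)
            continue
        for orientation in "+-":
            oriented = qseq if orientation == "+" else revcomp(qseq)
            qpos_all, qcodes = kmer_codes(encode(oriented), k)
            hit_i, ref_gpos = idx.lookup(qcodes)
            ci, local = idx.split_global(ref_gpos)
            anchors = _collapse_runs(qpos_all[hit_i], local, ci, k)
            if min_anchor is not None and min_anchor > k:
                anchors = [a for a in anchors if a[3] >= min_anchor]
            by_chrom: dict[int, list] = {}
            for a in anchors:
                by_chrom.setdefault(a[0], []).append(a)
            for c, group in by_chrom.items():
                rname = idx.chrom_names[c]
                rseq = ref.sequences[rname]
                for chain in _chain_anchors(group, max_anchor_gap):
                    blk = _chain_to_block(
                        chain, rseq, oriented, rname, qname, orientation, len(qseq)
                    )
                    if (blk.ref_len >= min_block and blk.qry_len >= min_block
                            and blk.identity >= min_identity):
                        blocks.append(blk)
    blocks.sort(key=lambda b: (b.ref_chrom, b.ref_start, b.qry_chrom, b.qry_start))
    return blocks


# ---------------------------------------------------------------------------
# block filters
# ---------------------------------------------------------------------------


def _sort_key(b: AlignmentBlock):
    # deterministic tie-break: longer block first, then smaller ref_start
    return (-b.ref_len, b.ref_chrom, b.ref_start, b.qry_chrom, b.qry_start)


def _wis_pass(blocks: list[AlignmentBlock], side: str,
              max_overlap: int = 0) -> list[AlignmentBlock]:
    """Maximum Σ(length x identity) subset non-overlapping on one genome
    (classic weighted interval scheduling, per chromosome).  Overlaps up to
    ``max_overlap`` bp are tolerated, as maximal exact anchors can extend a
    few bases past a rearrangement junction."""
    if side == "ref":
        chrom = lambda b: b.ref_chrom
        span = lambda b: (b.ref_start, b.ref_end)
    else:
        chrom = lambda b: b.qry_chrom
        span = lambda b: (b.qry_start, b.qry_end)
    groups: dict[str, list[AlignmentBlock]] = {}
    for b in blocks:
        groups.setdefault(chrom(b), []).append(b)
    kept: list[AlignmentBlock] = []
    for group in groups.values():
        group.sort(key=lambda b: (span(b)[1], span(b)[0], _sort_key(b)))
        ends = [span(b)[1] for b in group]
        n = len(group)
        dp = [0.0] * (n + 1)
        take = [False] * n
        for i in range(n):
            s, _ = span(group[i])
            p = bisect_right(ends, s + max_overlap, 0, i)
            with_i = dp[p] + group[i].score
            if with_i > dp[i] + 1e-12:
                dp[i + 1] = with_i
                take[i] = True
            else:
                dp[i + 1] = dp[i]
        i = n
        while i > 0:
            if take[i - 1]:
                kept.append(group[i - 1])
                s, _ = span(group[i - 1])
                i = bisect_right(ends, s + max_overlap, 0, i - 1)
            else:
                i -= 1
    kept.sort(key=lambda b: (b.ref_chrom, b.ref_start, b.qry_chrom, b.qry_start))
    return kept


def filter_one_to_one(blocks: list[AlignmentBlock],
                      max_overlap: int = 50) -> list[AlignmentBlock]:
    """Two-pass weighted interval scheduling: best-scoring block subset
    non-overlapping first on the reference and then on the query.
    Rearrangements (order or orientation changes) are permitted.
    """
    return _wis_pass(_wis_pass(list(blocks), "ref", max_overlap), "qry", max_overlap)


def filter_global(blocks: list[AlignmentBlock],
                  max_overlap: int = 50) -> list[AlignmentBlock]:
    """Per reference chromosome, the maximum-weight chain of forward blocks
    increasing in both reference and query coordinate (weighted longest
    increasing subsequence, overlaps up to ``max_overlap`` tolerated);
    everything off the chain is dropped.
    """
    pairs: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        if b.orientation == "+":
            pairs.setdefault((b.ref_chrom, b.qry_chrom), []).append(b)
    best_per_ref: dict[str, tuple[float, list[AlignmentBlock]]] = {}
    for (rname, _), group in pairs.items():
        group.sort(key=lambda b: (b.ref_start, b.ref_end, _sort_key(b)))
        n = len(group)
        dp = [0.0] * n
        prev = [-1] * n
        for i in range(n):
            bi = group[i]
            dp[i] = bi.score
            for j in range(i):
                bj = group[j]
                if (bj.ref_end <= bi.ref_start + max_overlap
                        and bj.qry_end <= bi.qry_start + max_overlap
                        and bj.ref_start < bi.ref_start
                        and bj.qry_start < bi.qry_start):
                    cand = dp[j] + bi.score
                    if cand > dp[i] + 1e-12:
                        dp[i] = cand
                        prev[i] = j
        if not n:
            continue
        end = int(np.argmax(dp))
        chain = []
        while end != -1:
            chain.append(group[end])
            end = prev[end]
        chain.reverse()
        weight = sum(b.score for b in chain)
        cur = best_per_ref.get(rname)
        if cur is None or weight > cur[0]:
            best_per_ref[rname] = (weight, chain)
    out = [b for _, chain in best_per_ref.values() for b in chain]
    out.sort(key=lambda b: (b.ref_chrom, b.ref_start))
    return out
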