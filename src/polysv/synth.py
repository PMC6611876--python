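"""Synthetic genomes, panels, mate pairs and genetic maps with known truth.

Every downstream stage of the pipeline is exercised against data built here:
a pair of ~Mb-scale "cultivar" genomes diverged by point mutations and short
indels and carrying engineered inversions, translocations and presence/
absence insertions; a subgenome/ancestor trio with planted homoeologous
introgression swaps; an accession panel split into two inversion-allele
groups; mate pairs drawn from either inversion haplotype; and a RIL genetic
map with suppressed recombination across the inversion.

All generators are deterministic: one integer seed feeds a named substream
per operation, so outputs are byte-identical across runs and stable under
reordering of calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dna import decode, encode, random_dna, revcomp
from .formats import GeneModel, GenomeSet

log = logging.getLogger("polysv")

# substream labels, hashed into the seed sequence per operation
_STREAMS = {"genome": 1, "panel": 2, "mates": 3, "rilmap": 4, "intro": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# requests and truth records
# ---------------------------------------------------------------------------


@dataclass
class SvRequest:
    """An engineered rearrangement, in coordinates of genome A."""

    kind: str  # inversion | intra_translocation | inter_translocation
    chrom: str
    start: int
    end: int
    dest_chrom: str | None = None
    dest_pos: int | None = None


@dataclass
class PavRequest:
    """An engineered presence/absence event.

    ``insertion`` adds novel sequence into genome B at ``start`` (B-specific
    presence); ``deletion`` removes A's ``[start, end)`` from genome B
    (A-specific presence).
    """

    kind: str  # insertion | deletion
    chrom: str
    start: int
    end: int = 0  # insertions: end == start
    length: int = 0  # insertions only


@dataclass
class PlantedVariant:
    chrom: str
    pos: int  # genome A coordinate
    kind: str  # snp | insertion | deletion
    ref: str
    alt: str
    length: int = 1
    pos_b: int | None = None  # final genome B coordinate of the edit anchor


@dataclass
class TruthSet:
    """Exact 0-based record of everything engineered into a simulation."""

    engineered_svs: list = field(default_factory=list)
    engineered_pavs: list = field(default_factory=list)
    introgression_spans: list = field(default_factory=list)
    planted_variants: list = field(default_factory=list)
    inversion_alleles: dict = field(default_factory=dict)
    inversion_span: tuple | None = None
    ril_truemap: list = field(default_factory=list)
    site_classes: np.ndarray | None = None

    def sv_spans(self, genome: str = "A") -> list[tuple[str, int, int]]:
        """Engineered SV spans on one genome ('A' reference, 'B' query)."""
        out = []
        for sv in self.engineered_svs:
            if genome == "A":
                out.append((sv["ref_chrom"], *sv["ref_span"]))
            else:
                out.append((sv["qry_chrom"], *sv["qry_span"]))
        for pav in self.engineered_pavs:
            if pav["carrier"] == genome:
                out.append((pav["chrom"], *pav["span"]))
            elif genome == "A" and pav["carrier"] == "B":
                # an insertion into B is a point on A; no span to exclude
                pass
        return out


# ---------------------------------------------------------------------------
# genome pair
# ---------------------------------------------------------------------------


class _Piece:
    """A building block of genome B: a slice of genome A (possibly reverse
    complemented) or a novel insert."""

    __slots__ = ("src_chrom", "src_start", "src_end", "strand", "novel", "tag")

    def __init__(self, src_chrom, src_start, src_end, strand="+", novel=None, tag=None):
        self.src_chrom = src_chrom
        self.src_start = src_start
        self.src_end = src_end
        self.strand = strand
        self.novel = novel
        self.tag = tag

    def __len__(self):
        if self.novel is not None:
            return len(self.novel)
        return self.src_end - self.src_start


def _validate_requests(lengths: dict[str, int], svs, pavs, flank: int = 1000):
    spans = []
    for r in svs:
        spans.append((r.chrom, r.start, r.end, r))
        if r.kind in ("intra_translocation", "inter_translocation"):
            dc = r.dest_chrom or r.chrom
            spans.append((dc, r.dest_pos, r.dest_pos + 1, r))
    for r in pavs:
        if r.kind == "deletion":
            spans.append((r.chrom, r.start, r.end, r))
        else:
            spans.append((r.chrom, r.start, r.start + 1, r))
    offenders = []
    by_chrom: dict[str, list] = {}
    for chrom, s, e, r in spans:
        if chrom not in lengths:
            offenders.append((r, "unknown chromosome"))
            continue
        if s < flank or e > lengths[chrom] - flank or s >= e:
            offenders.append((r, "span outside chromosome or within 1 kb flank"))
        by_chrom.setdefault(chrom, []).append((s, e, r))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1, r1), (s2, e2, r2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                offenders.append((r1, f"overlaps {r2}"))
    if offenders:
        msg = "; ".join(f"{r}: {why}" for r, why in offenders)
        raise ValueError(f"invalid engineered-event requests: {msg}")


def _find_run(pieces: dict[str, list[_Piece]], chrom: str, start: int, end: int):
    """Split pieces so that A:[start,end) maps to a contiguous run; return
    (host_chrom, i, j) with pieces[host][i:j] covering exactly that source."""
    for host, plist in pieces.items():
        for i, p in enumerate(plist):
            if p.novel is not None or p.src_chrom != chrom or p.strand != "+":
                continue
            if p.src_start <= start < p.src_end:
                # split left
                if p.src_start < start:
                    left = _Piece(chrom, p.src_start, start)
                    p.src_start = start
                    plist.insert(i, left)
                    i += 1
                # find piece containing end
                j = i
                while j < len(plist):
                    q = plist[j]
                    if q.novel is not None or q.src_chrom != chrom:
                        raise AssertionError("engineered run is not contiguous")
                    if q.src_end >= end:
                        if q.src_end > end:
                            right = _Piece(chrom, end, q.src_end)
                            q.src_end = end
                            plist.insert(j + 1, right)
                        return host, i, j + 1
                    j += 1
                raise AssertionError("run extends past chromosome end")
    raise AssertionError(f"source interval {chrom}:{start}-{end} not found")


def simulate_genome_pair(n_chrom: int = 2, chrom_len: int = 1_000_000,
                         snp_rate: float = 0.0, indel_rate: float = 0.0,
                         sv_spec: list[SvRequest] | None = None,
                         pav_spec: list[PavRequest] | None = None,
                         seed: int = 0,
                         boundary_margin: int = 100,
                         ) -> tuple[GenomeSet, GenomeSet, TruthSet]:
    """Build genome A and a derived genome B plus the exact truth.

    B is A with the requested inversions (reverse complement in place),
    translocations and PAV insertions/deletions applied, followed by point
    mutations and 1-10 bp indels at the given per-bp rates.  Planted small
    variants always fall outside engineered spans and at least
    ``boundary_margin`` bp away from any engineered junction or sequence end,
    so they are recoverable by alignment.
    """
    if not 0 <= snp_rate <= 0.05 or not 0 <= indel_rate <= 0.05:
        raise ValueError("snp_rate and indel_rate must lie in [0, 0.05]")
    sv_spec = list(sv_spec or [])
    pav_spec = list(pav_spec or [])
    rng = _rng(seed, "genome")
    chrom_names = [f"c{i + 1:02d}" for i in range(n_chrom)]
    a_seqs = {name: random_dna(rng, chrom_len) for name in chrom_names}
    genome_a = GenomeSet("genomeA", a_seqs)
    _validate_requests(genome_a.lengths, sv_spec, pav_spec)

    truth = TruthSet()
    pieces: dict[str, list[_Piece]] = {
        name: [_Piece(name, 0, chrom_len)] for name in chrom_names
    }

    # 1. inversions (in place, length preserving)
    tag = 0
    for r in sv_spec:
        if r.kind != "inversion":
            continue
        host, i, j = _find_run(pieces, r.chrom, r.start, r.end)
        run = pieces[host][i:j]
        for p in run:
            p.strand = "-"
            p.tag = ("sv", tag)
        pieces[host][i:j] = run[::-1]
        truth.engineered_svs.append(
            dict(kind="inversion", ref_chrom=r.chrom, ref_span=(r.start, r.end),
                 qry_chrom=r.chrom, qry_span=None, orientation="-", tag=tag)
        )
        tag += 1

    # 2. translocations (cut source run, reinsert at destination)
    for r in sv_spec:
        if r.kind not in ("intra_translocation", "inter_translocation"):
            continue
        host, i, j = _find_run(pieces, r.chrom, r.start, r.end)
        run = pieces[host][i:j]
        for p in run:
            p.tag = ("sv", tag)
        del pieces[host][i:j]
        dest_chrom = r.dest_chrom if r.kind == "inter_translocation" else r.chrom
        dhost, di, _ = _find_run(pieces, dest_chrom, r.dest_pos, r.dest_pos + 1)
        pieces[dhost][di:di] = run
        truth.engineered_svs.append(
            dict(kind=r.kind, ref_chrom=r.chrom, ref_span=(r.start, r.end),
                 qry_chrom=dest_chrom, qry_span=None, orientation="+", tag=tag)
        )
        tag += 1

    # 3. PAV deletions then insertions
    for r in pav_spec:
        if r.kind != "deletion":
            continue
        host, i, j = _find_run(pieces, r.chrom, r.start, r.end)
        del pieces[host][i:j]
        truth.engineered_pavs.append(
            dict(carrier="A", chrom=r.chrom, span=(r.start, r.end),
                 sequence=a_seqs[r.chrom][r.start:r.end], tag=None)
        )
    for r in pav_spec:
        if r.kind != "insertion":
            continue
        if r.length <= 100:
            raise ValueError("PAV insertions must be longer than 100 bp")
        seq = random_dna(rng, r.length, gc=0.4)
        host, i, _ = _find_run(pieces, r.chrom, r.start, r.start + 1)
        p = _Piece(None, 0, 0, novel=seq, tag=("pav", tag))
        pieces[host].insert(i, p)
        truth.engineered_pavs.append(
            dict(carrier="B", chrom=host, span=None, sequence=seq, tag=tag)
        )
        tag += 1

    # materialise B and record query-side spans of tagged runs
    b_seqs: dict[str, str] = {}
    tag_spans: dict[tuple, list[int]] = {}
    b_pos_of: dict[tuple[str, int], tuple[str, int]] = {}  # per-piece offsets
    piece_offsets: dict[str, list[tuple[_Piece, int]]] = {}
    for name, plist in pieces.items():
        parts = []
        off = 0
        offsets = []
        for p in plist:
            if p.novel is not None:
                parts.append(p.novel)
            else:
                s = a_seqs[p.src_chrom][p.src_start:p.src_end]
                parts.append(revcomp(s) if p.strand == "-" else s)
            if p.tag is not None:
                tag_spans.setdefault(p.tag, [off, off + len(p), name])
                span = tag_spans[p.tag]
                span[0] = min(span[0], off)
                span[1] = max(span[1], off + len(p))
            offsets.append((p, off))
            off += len(p)
        piece_offsets[name] = offsets
        b_seqs[name] = "".join(parts)
    # 4. plant SNPs and short indels outside engineered material
    edits: dict[str, list[tuple[int, str, str, str, int]]] = {n: [] for n in chrom_names}
    margin = boundary_margin
    for name, offsets in piece_offsets.items():
        for p, off in offsets:
            if p.tag is not None or p.novel is not None or p.strand == "-":
                continue
            lo, hi = p.src_start + margin, p.src_end - margin
            if hi - lo < 10:
                continue
            eligible = hi - lo
            n_snp = rng.binomial(eligible, snp_rate)
            n_ind = rng.binomial(eligible, indel_rate)
            n_total = n_snp + n_ind
            if n_total == 0:
                continue
            # positions spaced >= 13 bp so planted events never collide
            space = 13
            if space * n_total >= eligible:
                n_total = eligible // space
                n_snp = min(n_snp, n_total)
                n_ind = n_total - n_snp
            raw = np.sort(rng.choice(eligible - space * n_total, size=n_total,
                                     replace=False))
            pos = raw + space * np.arange(n_total) + lo
            which = rng.permutation(n_total) < n_snp
            for apos, is_snp in zip(pos, which):
                apos = int(apos)
                ref_base = a_seqs[p.src_chrom][apos]
                bpos = off + (apos - p.src_start)
                if is_snp:
                    alt = "ACGT"[(("ACGT".index(ref_base)) + int(rng.integers(1, 4))) % 4]
                    var = PlantedVariant(p.src_chrom, apos, "snp", ref_base, alt)
                    edits[name].append((bpos, "snp", ref_base, alt, 1, var))
                    truth.planted_variants.append(var)
                else:
                    ln = int(rng.integers(1, 11))
                    if rng.random() < 0.5:  # insertion into B
                        ins = random_dna(rng, ln)
                        var = PlantedVariant(p.src_chrom, apos, "insertion",
                                             "", ins, ln)
                        edits[name].append((bpos, "insertion", "", ins, ln, var))
                        truth.planted_variants.append(var)
                    else:  # deletion from B (bases of A removed)
                        if apos + 1 + ln > p.src_end - margin:
                            continue
                        dseq = a_seqs[p.src_chrom][apos + 1 : apos + 1 + ln]
                        var = PlantedVariant(p.src_chrom, apos, "deletion",
                                             dseq, "", ln)
                        edits[name].append((bpos, "deletion", dseq, "", ln, var))
                        truth.planted_variants.append(var)
    # engineered spans in final B coordinates: correct the pre-edit offsets
    # for the net length change of planted indels upstream of each span
    def _shift(chrom: str, x: int) -> int:
        delta = 0
        for bpos, kind, _, _, ln, _ in edits.get(chrom, []):
            if bpos >= x:
                break
            if kind == "insertion":
                delta += ln
            elif kind == "deletion":
                delta -= ln
        return x + delta

    for name in edits:
        edits[name].sort(key=lambda t: t[0])
    for sv in truth.engineered_svs:
        span = tag_spans.get(("sv", sv["tag"]))
        sv["qry_chrom"] = span[2]
        sv["qry_span"] = (_shift(span[2], span[0]), _shift(span[2], span[1]))
    for pav in truth.engineered_pavs:
        if pav["carrier"] == "B":
            span = tag_spans[("pav", pav["tag"])]
            pav["chrom"] = span[2]
            pav["span"] = (_shift(span[2], span[0]), _shift(span[2], span[1]))

    for name, elist in edits.items():
        if not elist:
            continue
        seq = b_seqs[name]
        out = []
        cur = 0
        delta = 0
        for bpos, kind, ref_al, alt_al, ln, var in elist:
            var.pos_b = bpos + delta
            if kind == "snp":
                out.append(seq[cur:bpos])
                out.append(alt_al)
                cur = bpos + 1
            elif kind == "insertion":
                out.append(seq[cur : bpos + 1])
                out.append(alt_al)
                cur = bpos + 1
                delta += ln
            else:  # deletion of [bpos+1, bpos+1+ln)
                out.append(seq[cur : bpos + 1])
                cur = bpos + 1 + ln
                delta -= ln
        out.append(seq[cur:])
        b_seqs[name] = "".join(out)

    genome_b = GenomeSet("genomeB", b_seqs)
    return genome_a, genome_b, truth


# ---------------------------------------------------------------------------
# subgenome / ancestor trio with introgression swaps
# ---------------------------------------------------------------------------


def _mutate_snps(seq: str, rate: float, rng: np.random.Generator) -> str:
    codes = encode(seq).copy()
    n = len(codes)
    k = rng.binomial(n, rate)
    pos = rng.choice(n, size=k, replace=False)
    shift = rng.integers(1, 4, size=k).astype(np.uint8)
    sel = codes[pos] < 4
    codes[pos[sel]] = (codes[pos[sel]] + shift[sel]) % 4
    return decode(codes)


def simulate_introgression_trio(chrom_len: int = 2_000_000,
                                swap_spans: list[tuple[int, int]] | None = None,
                                own_divergence: float = 0.02,
                                ancestor_divergence: float = 0.05,
                                seed: int = 0,
                                ) -> tuple[GenomeSet, GenomeSet, GenomeSet, TruthSet]:
    """A subgenome plus its two candidate ancestors, with planted swaps.

    Both ancestors derive from a common base at ``ancestor_divergence`` each
    (so they sit ~2x that apart); the subgenome derives from the 'own'
    ancestor at ``own_divergence``, except inside the swap spans, which are
    copied from the 'other' ancestor before the final divergence step.
    """
    if swap_spans is None:
        swap_spans = [(500_000, 550_000), (1_200_000, 1_260_000)]
    rng = _rng(seed, "intro")
    base = random_dna(rng, chrom_len)
    own = _mutate_snps(base, ancestor_divergence, rng)
    other = _mutate_snps(base, ancestor_divergence, rng)
    sub = list(own)
    for s, e in swap_spans:
        sub[s:e] = other[s:e]
    sub = _mutate_snps("".join(sub), own_divergence, rng)
    truth = TruthSet(
        introgression_spans=[("c01", (s, e), "other") for s, e in swap_spans]
    )
    return (
        GenomeSet("subgenome", {"c01": sub}),
        GenomeSet("ancestor_own", {"c01": own}),
        GenomeSet("ancestor_other", {"c01": other}),
        truth,
    )


# ---------------------------------------------------------------------------
# accession panel
# ---------------------------------------------------------------------------


def simulate_panel(n_ref_like: int = 66, n_alt_like: int = 348,
                   n_sites: int = 20_000,
                   group_private_fraction: float = 0.6,
                   inside_inversion_diversity_scale: float = 0.2,
                   seed: int = 0,
                   chrom: str = "c08", chrom_len: int = 30_000_000,
                   inversion_span: tuple[int, int] = (12_000_000, 20_000_000),
                   het_rate: float = 0.01, missing_rate: float = 0.02):
    """Accession panel structured by a chromosomal inversion.

    Sites outside the inversion are drawn from one shared allele-frequency
    vector.  Inside the inversion, a ``group_private_fraction`` of sites is
    haplotype-structured (half fixed differences between the two inversion
    allele groups, half polymorphic in a single group); within-group minor
    allele frequencies inside the inversion are multiplied by
    ``inside_inversion_diversity_scale``, emulating the reduced diversity of
    a non-recombining haplotype.  Group sizes default to the 66 / 348 split
    of reference-like vs alternate-like accessions.

    Returns ``(GenotypeMatrix, TruthSet)``; genotypes are inbred-coded
    (dosage 0/2) with small heterozygous and missing call rates.
    """
    from .popgen import GenotypeMatrix

    if n_ref_like < 2 or n_alt_like < 2:
        raise ValueError("both groups need at least 2 accessions")
    if n_sites < 10:
        raise ValueError("n_sites must be >= 10")
    if not 0 <= group_private_fraction <= 1:
        raise ValueError("group_private_fraction must lie in [0, 1]")
    rng = _rng(seed, "panel")
    n = n_ref_like + n_alt_like
    accessions = [f"R{i:03d}" for i in range(n_ref_like)] + [
        f"Z{i:03d}" for i in range(n_alt_like)
    ]
    groups = {a: ("ref_like" if a.startswith("R") else "alt_like") for a in accessions}
    positions = np.sort(rng.choice(chrom_len, size=n_sites, replace=False))
    inside = (positions >= inversion_span[0]) & (positions < inversion_span[1])
    scale = inside_inversion_diversity_scale

    freq_ref = np.empty(n_sites)
    freq_alt = np.empty(n_sites)
    site_class = np.full(n_sites, "shared", dtype=object)
    shared = rng.uniform(0.05, 0.95, size=n_sites)
    minor = np.minimum(shared, 1 - shared)
    freq_ref[:] = minor
    freq_alt[:] = minor
    # inside the inversion: shrink within-group diversity, add structure
    freq_ref[inside] = minor[inside] * scale
    freq_alt[inside] = minor[inside] * scale
    structured = inside & (rng.random(n_sites) < group_private_fraction)
    idx = np.nonzero(structured)[0]
    half = rng.random(len(idx)) < 0.5
    u = rng.uniform(0.0, 0.3, size=len(idx)) * scale
    # fixed differences: ref-like consensus 0, alt-like consensus 1
    fixed = idx[half]
    freq_ref[fixed] = u[half]
    freq_alt[fixed] = 1 - u[half]
    site_class[fixed] = "fixed_diff"
    # group-private polymorphisms around a shared consensus of 0
    priv = idx[~half]
    which_ref = rng.random(len(priv)) < 0.5
    freq_ref[priv] = np.where(which_ref, u[~half], 0.0)
    freq_alt[priv] = np.where(which_ref, 0.0, u[~half])
    site_class[priv] = np.where(which_ref, "private_ref", "private_alt")

    geno = np.empty((n, n_sites), dtype=np.int8)
    geno[:n_ref_like] = (rng.random((n_ref_like, n_sites)) < freq_ref) * 2
    geno[n_ref_like:] = (rng.random((n_alt_like, n_sites)) < freq_alt) * 2
    if het_rate > 0:
        geno[rng.random(geno.shape) < het_rate] = 1
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = -1

    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "T"}
    )
    matrix = GenotypeMatrix(accessions, sites, geno, groups=groups)
    truth = TruthSet(
        inversion_alleles=groups,
        inversion_span=(chrom, *inversion_span),
        site_classes=np.asarray(site_class),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# mate pairs near inversion breakpoints
# ---------------------------------------------------------------------------

MATE_COLUMNS = ["accession", "chrom", "pos1", "strand1", "pos2", "strand2", "read_len"]


def simulate_mate_pairs(chrom: str, chrom_len: int,
                        inversion_span: tuple[int, int],
                        haplotype: str,
                        n_pairs: int = 20,
                        insert_mean: int = 3000, insert_sd: int = 300,
                        read_len: int = 150, seed: int = 0,
                        accession: str = "acc") -> pd.DataFrame:
    """Mate pairs drawn around both inversion breakpoints from one haplotype,
    reported as mapped coordinates on the *reference* haplotype.

    The alternate haplotype is the reference with ``inversion_span`` reverse
    complemented; reads that fall entirely inside the inverted segment map
    back mirrored and strand-flipped, which is what makes breakpoint-spanning
    pairs from the alternate haplotype discordant.  Reads that would straddle
    a junction (split alignments) are dropped.
    """
    if haplotype not in ("ref", "alt"):
        raise ValueError("haplotype must be 'ref' or 'alt'")
    if insert_mean <= 2 * read_len:
        raise ValueError("insert_mean must exceed twice the read length")
    s, e = inversion_span
    rng = _rng(seed, "mates")
    rows = []
    for bp in (s, e):
        if bp < read_len or bp > chrom_len - read_len:
            log.warning("breakpoint %d within a read length of the contig end; "
                        "skipped", bp)
            continue
        for _ in range(n_pairs):
            frag = max(int(rng.normal(insert_mean, insert_sd)), 2 * read_len + 2)
            start = int(rng.integers(bp - frag + 1, bp))
            if start < 0 or start + frag > chrom_len:
                continue
            r1 = (start, start + read_len, "+")
            r2 = (start + frag - read_len, start + frag, "-")
            if haplotype == "alt":
                r1 = _map_alt_read(r1, s, e)
                r2 = _map_alt_read(r2, s, e)
                if r1 is None or r2 is None:
                    continue
            rows.append(
                (accession, chrom, r1[0], r1[2], r2[0], r2[2], read_len)
            )
    return pd.DataFrame(rows, columns=MATE_COLUMNS)


def _map_alt_read(read, s, e):
    a, b, strand = read
    if b <= s or a >= e:
        return read
    if a >= s and b <= e:  # fully inside: mirror and flip
        return (s + e - b, s + e - a, "-" if strand == "+" else "+")
    return None  # straddles a junction


def write_mate_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_mate_pairs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# RIL genetic map
# ---------------------------------------------------------------------------


def simulate_ril_map(chrom_len: int = 10_000_000, n_bins: int = 100,
                     baseline_rate: float = 1.0,
                     suppressed_span: tuple[int, int] | None = None,
                     suppression_factor: float = 1.0,
                     seed: int = 0, chrom: str = "c08") -> pd.DataFrame:
    """Cumulative genetic map over evenly spaced bins.

    ``baseline_rate`` is in cM/Mb; inter-bin cM increments that fall inside
    ``suppressed_span`` are scaled by ``suppression_factor`` (pro-rated for
    partial overlap), emulating recombination suppression across an
    inversion.  Columns: chrom, pos (bp), cm (cumulative).
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    if not 0 <= suppression_factor <= 1:
        raise ValueError("suppression_factor must lie in [0, 1]")
    positions = np.linspace(0, chrom_len, n_bins).round().astype(int)
    s, e = suppressed_span if suppressed_span else (0, 0)

    def seg_cm(a: int, b: int) -> float:
        inside = max(0, min(b, e) - max(a, s))
        outside = (b - a) - inside
        return baseline_rate * (outside + inside * suppression_factor) / 1e6

    cm = np.concatenate(
        [[0.0], np.cumsum([seg_cm(a, b) for a, b in zip(positions, positions[1:])])]
    )
    return pd.DataFrame({"chrom": chrom, "pos": positions, "cm": cm})


# ---------------------------------------------------------------------------
# synthetic gene embedding (for PAV-gene and ortholog tests)
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")


def make_gene_sequence(rng: np.random.Generator, exon_lens: list[int],
                       intron_lens: list[int]) -> tuple[str, GeneModel]:
    """Random single-strand gene: ATG...stop CDS split over exons, canonical
    GT/AG introns, no internal stop codons.  Returns the genomic sequence of
    the locus and a GeneModel with coordinates local to that sequence."""
    if len(intron_lens) != len(exon_lens) - 1:
        raise ValueError("need one fewer intron than exons")
    cds_len = sum(exon_lens)
    if cds_len % 3 or cds_len < 9:
        raise ValueError("total exon length must be a multiple of 3 and >= 9")
    n_codons = cds_len // 3
    codons = []
    bases = "ACGT"
    while len(codons) < n_codons - 1:
        c = "".join(bases[rng.integers(4)] for _ in range(3))
        if c not in _STOPS:
            codons.append(c)
    cds = "ATG" + "".join(codons[1:]) + _STOPS[int(rng.integers(3))]
    seq_parts = []
    exons, cdss = [], []
    pos = 0
    cursor = 0
    for i, ln in enumerate(exon_lens):
        seq_parts.append(cds[cursor : cursor + ln])
        exons.append((pos, pos + ln))
        cdss.append((pos, pos + ln))
        cursor += ln
        pos += ln
        if i < len(intron_lens):
            iln = intron_lens[i]
            if iln < 10:
                raise ValueError("introns must be >= 10 bp")
            mid = random_dna(rng, iln - 4)
            seq_parts.append("GT" + mid + "AG")
            pos += iln
    seq = "".join(seq_parts)
    model = GeneModel("gene", "local", "+", exons, cdss)
    return seq, model


def embed_gene(sequences: dict[str, str], chrom: str, start: int,
               gene_id: str, rng: np.random.Generator,
               exon_lens: list[int] | None = None,
               intron_lens: list[int] | None = None) -> GeneModel:
    """Write a synthetic gene into a mutable genome dict at ``start`` and
    return its model in chromosome coordinates (forward strand)."""
    exon_lens = exon_lens or [300, 300, 300]
    intron_lens = intron_lens if intron_lens is not None else [120] * (len(exon_lens) - 1)
    seq, local = make_gene_sequence(rng, exon_lens, intron_lens)
    s = sequences[chrom]
    sequences[chrom] = s[:start] + seq + s[start + len(seq):]
    shift = lambda ivs: [(a + start, b + start) for a, b in ivs]
    return GeneModel(gene_id, chrom, "+", shift(local.exons), shift(local.cds))
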