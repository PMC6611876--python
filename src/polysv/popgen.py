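"""Panel-scale population genetics: site filtering, inversion-breakpoint
genotyping from mate pairs, windowed diversity/differentiation/haplotype
statistics, private SNPs, neighbour-joining grouping, and recombination-rate
windows from a genetic map.

Accessions are treated as highly inbred (each close to one haplotype):
genotypes are alt-allele dosages 0/1/2 with -1 for missing, allele
frequencies use dosage/2, and the allele sample size per site is the number
of called accessions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("polysv")


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic sites, alt-dosage coded (0/1/2, -1 missing)."""

    accessions: list[str]
    sites: pd.DataFrame  # columns: chrom, pos, ref, alt
    genotypes: np.ndarray
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.accessions) or m != len(self.sites):
            raise ValueError("genotype matrix dimensions disagree with labels")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted on {chrom}")

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.accessions, self.sites[mask].reset_index(drop=True),
            self.genotypes[:, mask], self.groups,
        )

    def subset_accessions(self, names: list[str]) -> "GenotypeMatrix":
        idx = [self.accessions.index(a) for a in names]
        return GenotypeMatrix(
            list(names), self.sites, self.genotypes[idx],
            {a: self.groups[a] for a in names} if self.groups else None,
        )

    def group_indices(self, groups: dict[str, str] | None = None
                      ) -> dict[str, np.ndarray]:
        groups = groups or self.groups
        if not groups:
            raise ValueError("no group labels available")
        out: dict[str, list[int]] = {}
        for i, a in enumerate(self.accessions):
            if a in groups:
                out.setdefault(groups[a], []).append(i)
        return {g: np.asarray(ix) for g, ix in out.items()}

    # -- VCF I/O ------------------------------------------------------------

    def to_vcf(self, path, contig_lengths: dict[str, int] | None = None) -> None:
        from .formats import write_vcf

        contigs = contig_lengths or {
            c: int(sub["pos"].max()) + 1 for c, sub in self.sites.groupby("chrom")
        }
        variants = list(
            zip(self.sites["chrom"], self.sites["pos"], self.sites["ref"],
                self.sites["alt"])
        )
        write_vcf(variants, contigs, path, sample_genotypes=self.genotypes,
                  samples=self.accessions)

    @classmethod
    def from_vcf(cls, path, groups: dict[str, str] | None = None
                 ) -> "GenotypeMatrix":
        """Read a biallelic-SNP VCF into a matrix (multi-allelic sites are
        skipped with a warning)."""
        from cyvcf2 import VCF

        reader = VCF(str(path), gts012=True)
        accessions = list(reader.samples)
        rows, geno = [], []
        for var in reader:
            if len(var.ALT) != 1:
                log.warning("skipping multi-allelic site %s:%d", var.CHROM,
                            var.POS)
                continue
            rows.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0]))
            codes = var.gt_types.astype(np.int8)  # 0/1/2, 3 = missing
            codes[codes == 3] = -1
            geno.append(codes)
        sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        matrix = (np.asarray(geno, dtype=np.int8).T if geno
                  else np.empty((len(accessions), 0), np.int8))
        return cls(accessions, sites, matrix, groups)


# ---------------------------------------------------------------------------
# site-level helpers
# ---------------------------------------------------------------------------


def _site_stats(g: np.ndarray):
    called = g >= 0
    n_called = called.sum(axis=0)
    dosage = np.where(called, g, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, dosage / (2.0 * n_called), np.nan)
    return called, n_called, p


def filter_sites(m: GenotypeMatrix, maf_min: float = 0.05,
                 het_max: float = 0.10, miss_max: float = 0.10
                 ) -> GenotypeMatrix:
    """Drop sites failing the MAF / heterozygosity / missingness thresholds
    (all computed on non-missing calls)."""
    g = m.genotypes
    called, n_called, p = _site_stats(g)
    maf = np.minimum(p, 1 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        het = np.where(n_called > 0, (g == 1).sum(axis=0) / n_called, 1.0)
    miss = 1.0 - n_called / g.shape[0]
    keep = (maf >= maf_min) & (het <= het_max) & (miss <= miss_max)
    keep &= ~np.isnan(maf)
    if not keep.any():
        log.warning("all %d sites removed by filters", m.n_sites)
    return m.subset_sites(keep)


# ---------------------------------------------------------------------------
# windowed statistics
# ---------------------------------------------------------------------------


def _windows(positions: np.ndarray, values: np.ndarray, window: int,
             step: int, denom: float, chrom: str, statistic: str
             ) -> pd.DataFrame:
    """Sliding-window sums of per-site values divided by ``denom``."""
    if len(positions) == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "statistic", "value", "n_sites"]
        )
    cum = np.concatenate([[0.0], np.cumsum(values)])
    last = int(positions.max())
    starts = np.arange(0, last + 1, step)
    lo = np.searchsorted(positions, starts)
    hi = np.searchsorted(positions, starts + window)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window,
            "statistic": statistic,
            "value": (cum[hi] - cum[lo]) / denom,
            "n_sites": hi - lo,
        }
    )


def pi_windows(m: GenotypeMatrix, window: int = 1_000_000,
               step: int = 10_000) -> pd.DataFrame:
    """Nucleotide diversity per sliding window.

    Per-site π is the unbiased expected heterozygosity 2p̂q̂·n/(n−1) over
    non-missing calls; the window value is the per-site sum divided by the
    window length in bp.
    """
    if m.n_accessions < 2:
        raise ValueError("pi requires at least two accessions")
    _, n_called, p = _site_stats(m.genotypes)
    with np.errstate(divide="ignore", invalid="ignore"):
        site_pi = np.where(
            n_called > 1, 2.0 * p * (1 - p) * n_called / (n_called - 1), 0.0
        )
    out = []
    for chrom, sub in m.sites.groupby("chrom", sort=False):
        ix = sub.index.to_numpy()
        out.append(
            _windows(sub["pos"].to_numpy(), site_pi[ix], window, step,
                     float(window), chrom, "pi")
        )
    return pd.concat(out, ignore_index=True)


def _wc_components(g1: np.ndarray, g2: np.ndarray):
    """Weir & Cockerham (1984) per-site variance components a, b, c for two
    populations of diploid-coded individuals."""
    comps = []
    for g in (g1, g2):
        called = g >= 0
        n = called.sum(axis=0).astype(float)
        dose = np.where(called, g, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, dose / (2 * n), np.nan)
            h = np.where(n > 0, np.where(called, g == 1, False).sum(axis=0) / n, np.nan)
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nsum = n1 + n2
    nbar = nsum / r
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (nsum - (n1 ** 2 + n2 ** 2) / nsum) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    valid = (n1 > 1) & (n2 > 1) & ~np.isnan(pbar)
    return np.where(valid, a, 0.0), np.where(valid, b, 0.0), np.where(valid, c, 0.0)


def fst_windows(m: GenotypeMatrix, groups: dict[str, str] | None = None,
                window: int = 1_000_000, step: int = 100_000) -> pd.DataFrame:
    """Weir–Cockerham weighted F_ST per sliding window: the window value is
    Σa / Σ(a+b+c) over the sites it contains."""
    gix = m.group_indices(groups)
    if len(gix) != 2:
        raise ValueError(f"need exactly two groups, got {sorted(gix)}")
    (ix1, ix2) = gix.values()
    if len(ix1) < 2 or len(ix2) < 2:
        raise ValueError("both groups need at least two accessions")
    a, b, c = _wc_components(m.genotypes[ix1], m.genotypes[ix2])
    out = []
    for chrom, sub in m.sites.groupby("chrom", sort=False):
        ix = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        num = _windows(pos, a[ix], window, step, 1.0, chrom, "fst")
        den = _windows(pos, (a + b + c)[ix], window, step, 1.0, chrom, "fst")
        with np.errstate(divide="ignore", invalid="ignore"):
            num["value"] = np.where(
                den["value"] != 0, num["value"] / den["value"], 0.0
            )
        out.append(num)
    return pd.concat(out, ignore_index=True)


def fst_per_site(m: GenotypeMatrix, groups: dict[str, str] | None = None
                 ) -> np.ndarray:
    """Per-site Weir–Cockerham θ (a / (a+b+c)); NaN where undefined."""
    gix = m.group_indices(groups)
    (ix1, ix2) = gix.values()
    a, b, c = _wc_components(m.genotypes[ix1], m.genotypes[ix2])
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(a + b + c != 0, a / (a + b + c), np.nan)


def hapdiv_windows(m: GenotypeMatrix, cluster_window: int = 10_000,
                   avg_window: int = 1_000_000, step: int = 100_000,
                   accessions: list[str] | None = None) -> pd.DataFrame:
    """Haplotype diversity: accessions are clustered by identical genotype
    vectors within each ``cluster_window`` tile (an accession with a missing
    call matches nothing and forms its own cluster); tile diversity is
    (n/(n−1))(1 − Σ fᵢ²) over cluster frequencies, and tiles are averaged
    within each sliding ``avg_window``.  Tiles without sites are skipped.
    """
    sub = m.subset_accessions(accessions) if accessions else m
    n = sub.n_accessions
    if n < 2:
        raise ValueError("haplotype diversity requires >= 2 accessions")
    out = []
    for chrom, sdf in sub.sites.groupby("chrom", sort=False):
        pos = sdf["pos"].to_numpy()
        ix = sdf.index.to_numpy()
        tiles = np.unique(pos // cluster_window)
        tile_pos, tile_div = [], []
        for t in tiles:
            in_tile = ix[(pos // cluster_window) == t]
            g = sub.genotypes[:, in_tile]
            has_missing = (g < 0).any(axis=1)
            counts: dict = {}
            for i in range(n):
                key = ("missing", i) if has_missing[i] else tuple(g[i])
                counts[key] = counts.get(key, 0) + 1
            f = np.array(list(counts.values())) / n
            tile_pos.append(t * cluster_window)
            tile_div.append((n / (n - 1)) * (1 - np.sum(f ** 2)))
        tile_pos = np.asarray(tile_pos)
        tile_div = np.asarray(tile_div)
        starts = np.arange(0, int(pos.max()) + 1, step)
        lo = np.searchsorted(tile_pos, starts)
        hi = np.searchsorted(tile_pos, starts + avg_window)
        cum = np.concatenate([[0.0], np.cumsum(tile_div)])
        cnt = hi - lo
        with np.errstate(divide="ignore", invalid="ignore"):
            val = np.where(cnt > 0, (cum[hi] - cum[lo]) / np.maximum(cnt, 1), np.nan)
        out.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + avg_window,
                 "statistic": "hap_div", "value": val, "n_sites": cnt}
            )
        )
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# private / common SNPs
# ---------------------------------------------------------------------------


def private_common_snps(m: GenotypeMatrix, groups: dict[str, str] | None = None,
                        seed: int = 0) -> dict[str, int]:
    """Common vs group-private segregating sites after down-sampling the
    larger group to the smaller group's size.

    A site carries the SNP in a group when at least one called accession in
    that group carries the alternate allele.
    """
    gix = m.group_indices(groups)
    if len(gix) != 2:
        raise ValueError("need exactly two groups")
    (name1, ix1), (name2, ix2) = sorted(gix.items())
    rng = np.random.default_rng(seed)
    k = min(len(ix1), len(ix2))
    ix1 = rng.choice(ix1, size=k, replace=False) if len(ix1) > k else ix1
    ix2 = rng.choice(ix2, size=k, replace=False) if len(ix2) > k else ix2
    has1 = (m.genotypes[ix1] > 0).any(axis=0)
    has2 = (m.genotypes[ix2] > 0).any(axis=0)
    return {
        "common": int((has1 & has2).sum()),
        f"private_{name1}": int((has1 & ~has2).sum()),
        f"private_{name2}": int((~has1 & has2).sum()),
        "n_downsampled": int(k),
    }


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------


def genotype_distances(m: GenotypeMatrix) -> np.ndarray:
    """Pairwise proportion of differing genotypes over mutually called sites."""
    g = m.genotypes
    n = m.n_accessions
    d = np.zeros((n, n))
    called = g >= 0
    for i in range(n):
        both = called[i] & called
        diff = (g[i] != g) & both
        nb = both.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d[i] = np.where(nb > 0, diff.sum(axis=1) / nb, 0.0)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2


def nj_groups(m: GenotypeMatrix) -> tuple[str, dict[str, int]]:
    """Canonical neighbour joining on genotype distances, plus the two-way
    cut induced by the tree's longest internal branch.

    Returns ``(newick, accession -> cluster index)``.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if m.n_accessions < 3:
        raise ValueError("neighbour joining needs >= 3 accessions")
    dm = DistanceMatrix(genotype_distances(m), ids=m.accessions)
    tree = nj(dm)
    best, best_len = None, -1.0
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        length = node.length or 0.0
        if length > best_len:
            best, best_len = node, length
    if best is None:  # star-like: fall back to the longest terminal branch
        best = max(
            tree.tips(), key=lambda t: ((t.length or 0.0), t.name)
        )
    side = {t.name for t in best.tips()} if not best.is_tip() else {best.name}
    cut = {a: (1 if a in side else 0) for a in m.accessions}
    return str(tree).strip(), cut


# ---------------------------------------------------------------------------
# breakpoint genotyping from mate pairs
# ---------------------------------------------------------------------------


@dataclass
class BreakpointCall:
    accession: str
    sv_id: str
    allele: str  # ref_like | alt_like | unassigned
    n_span_concordant: int
    n_span_discordant: int


def genotype_breakpoints(pairs: pd.DataFrame,
                         breakpoints: list[tuple[str, str, int]],
                         insert_mean: int, insert_sd: int,
                         min_support: int = 2,
                         chrom_lengths: dict[str, int] | None = None
                         ) -> list[BreakpointCall]:
    """Assign an inversion allele per accession per breakpoint.

    ``breakpoints`` lists (sv_id, chrom, position).  A mate pair whose
    fragment spans a breakpoint counts as concordant (reference-like
    evidence) when the mates point inward (+/-) with a separation within
    mean ± 4 sd, and as discordant (alternate-like evidence) when the mates
    map to the same strand or at an out-of-range separation.  An allele is
    called only when the evidence is unanimous with at least ``min_support``
    spanning pairs; otherwise the accession is left unassigned.
    """
    for sv_id, chrom, bp in breakpoints:
        if chrom_lengths is not None:
            if chrom not in chrom_lengths or not 0 <= bp < chrom_lengths[chrom]:
                raise ValueError(f"breakpoint {sv_id} at {chrom}:{bp} is not on "
                                 "the reference")
    lo, hi = insert_mean - 4 * insert_sd, insert_mean + 4 * insert_sd
    calls = []
    for accession, sub in pairs.groupby("accession", sort=True):
        p1 = sub[["pos1", "strand1"]].to_numpy()
        p2 = sub[["pos2", "strand2"]].to_numpy()
        rl = sub["read_len"].to_numpy()
        left_first = sub["pos1"].to_numpy() <= sub["pos2"].to_numpy()
        lpos = np.where(left_first, p1[:, 0], p2[:, 0]).astype(int)
        rpos = np.where(left_first, p2[:, 0], p1[:, 0]).astype(int)
        lstr = np.where(left_first, p1[:, 1], p2[:, 1])
        rstr = np.where(left_first, p2[:, 1], p1[:, 1])
        span_len = rpos + rl - lpos
        concordant = (lstr == "+") & (rstr == "-") & (span_len >= lo) & (span_len <= hi)
        chroms = sub["chrom"].to_numpy()
        for sv_id, chrom, bp in breakpoints:
            spanning = (chroms == chrom) & (lpos < bp) & (rpos + rl > bp)
            n_conc = int((spanning & concordant).sum())
            n_disc = int((spanning & ~concordant).sum())
            if n_conc >= min_support and n_disc == 0:
                allele = "ref_like"
            elif n_disc >= min_support and n_conc == 0:
                allele = "alt_like"
            else:
                allele = "unassigned"
            calls.append(BreakpointCall(accession, sv_id, allele, n_conc, n_disc))
    return calls


def combine_breakpoint_calls(calls: list[BreakpointCall]) -> pd.DataFrame:
    """Per-accession table of per-SV calls plus a combined call (unassigned
    on any contradiction between assigned SVs)."""
    df = pd.DataFrame(
        [(c.accession, c.sv_id, c.allele, c.n_span_concordant,
          c.n_span_discordant) for c in calls],
        columns=["accession", "sv_id", "allele", "n_concordant", "n_discordant"],
    )
    combined = []
    for accession, sub in df.groupby("accession", sort=True):
        assigned = set(sub["allele"]) - {"unassigned"}
        if len(assigned) == 1:
            combined.append((accession, assigned.pop()))
        else:
            combined.append((accession, "unassigned"))
    wide = df.pivot(index="accession", columns="sv_id", values="allele")
    lookup = dict(combined)
    wide["combined"] = [lookup[a] for a in wide.index]
    return wide.reset_index()


# ---------------------------------------------------------------------------
# recombination-rate windows
# ---------------------------------------------------------------------------


def recomb_windows(genetic_map: pd.DataFrame, window: int = 1_000_000,
                   step: int = 500_000) -> tuple[pd.DataFrame, float]:
    """cM/Mb per sliding window from a cumulative genetic map (columns
    chrom, pos, cm), pro-rating inter-bin intervals linearly; also returns
    the map-wide mean cM per bin.
    """
    out = []
    total_cm = 0.0
    n_bins = 0
    for chrom, sub in genetic_map.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=float)
        cm = sub["cm"].to_numpy(dtype=float)
        deltas = np.diff(cm)
        if (deltas < 0).any():
            bad = int(np.nonzero(deltas < 0)[0][0]) + 1
            raise ValueError(
                f"non-monotone cM at bin {bad} ({chrom}:{int(pos[bad])})"
            )
        total_cm += cm[-1] - cm[0]
        n_bins += len(sub)
        starts = np.arange(0, int(pos.max()) + 1, step)
        cm_start = np.interp(starts, pos, cm)
        cm_end = np.interp(starts + window, pos, cm)
        out.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + window,
                 "statistic": "cm_per_mb",
                 "value": (cm_end - cm_start) / (window / 1e6),
                 "n_sites": [
                     int(((pos >= s) & (pos < s + window)).sum()) for s in starts
                 ]}
            )
        )
    mean_cm_per_bin = total_cm / n_bins if n_bins else 0.0
    return pd.concat(out, ignore_index=True), mean_cm_per_bin


def mean_cm_per_bin(total_cm: float, n_bins: int) -> float:
    """Mean map density (cM per bin) from map totals."""
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    return total_cm / n_bins
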