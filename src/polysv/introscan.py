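"""Homoeologous introgression detection by binned coverage-ratio scoring of a
subgenome against its own and the other subgenome's ancestral diploid.

The rule is deliberately simple: chop the subgenome into 5-kb bins, measure
how much of each bin aligns to either ancestor, and call introgression where
the other-ancestor coverage is at least 1.5-fold the own-ancestor coverage
(or where the own ancestor shows nothing at all and the other covers the
bin well).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import ReferenceIndex, seed_and_chain
from .formats import GenomeSet

log = logging.getLogger("polysv")


@dataclass
class IntrogressionBin:
    subgenome: str
    chromosome: str
    start: int
    end: int
    cov_own: float
    cov_other: float
    ratio: float  # inf-like cases use cov_other / max(cov_own, eps) semantics
    call: str  # introgressed | native | unresolved
    terminal: bool = False
    zero_denominator: bool = False


def _coverage_per_bin(genome: GenomeSet, ancestor: GenomeSet, k: int,
                      min_ident: float, min_seed: int, bin_size: int,
                      max_anchor_gap: int) -> dict[str, np.ndarray]:
    """Fraction of each bin aligned to the ancestor (union over blocks that
    pass the identity and minimum-length thresholds)."""
    blocks = seed_and_chain(
        ancestor, genome, k=k, max_anchor_gap=max_anchor_gap,
        min_block=min_seed, min_identity=min_ident, min_anchor=min_seed,
    )
    out: dict[str, np.ndarray] = {}
    for chrom, length in genome.lengths.items():
        n_bins = -(-length // bin_size)
        cov = np.zeros(length, dtype=bool)
        for b in blocks:
            if b.qry_chrom == chrom:
                cov[b.qry_start : b.qry_end] = True
        per_bin = np.add.reduceat(cov.astype(np.int64),
                                  np.arange(0, length, bin_size))
        sizes = np.full(n_bins, bin_size)
        if length % bin_size:
            sizes[-1] = length % bin_size
        out[chrom] = per_bin / sizes
    return out


def score_bins(subgenome: GenomeSet, own_ancestor: GenomeSet,
               other_ancestor: GenomeSet, bin_size: int = 5000,
               min_ident: float = 0.9, min_seed: int = 50,
               min_target_cov: float = 0.7, ratio_min: float = 1.5,
               k: int = 21, max_anchor_gap: int = 2000,
               ) -> list[IntrogressionBin]:
    """Score every ``bin_size`` bin of the subgenome against both ancestors.

    A bin whose coverage is below ``min_target_cov`` in both ancestors is
    unresolved; otherwise it is called introgressed when
    ``cov_other / cov_own >= ratio_min``, including the degenerate case of
    zero own-ancestor coverage with ``cov_other >= min_target_cov`` (a zero
    denominator is the strongest possible signal and is flagged as such).
    All-N bins are unresolved; terminal short bins are scored but flagged.
    """
    cov_own_all = _coverage_per_bin(
        subgenome, own_ancestor, k, min_ident, min_seed, bin_size, max_anchor_gap
    )
    cov_oth_all = _coverage_per_bin(
        subgenome, other_ancestor, k, min_ident, min_seed, bin_size, max_anchor_gap
    )
    bins: list[IntrogressionBin] = []
    for chrom, length in subgenome.lengths.items():
        seq = subgenome.sequences[chrom]
        for i, (co, cx) in enumerate(zip(cov_own_all[chrom], cov_oth_all[chrom])):
            s = i * bin_size
            e = min(s + bin_size, length)
            terminal = e - s < bin_size
            zero_den = False
            if set(seq[s:e]) <= {"N"}:
                call, ratio = "unresolved", 0.0
            elif co < min_target_cov and cx < min_target_cov:
                call, ratio = "unresolved", 0.0
            elif co == 0.0:
                zero_den = True
                ratio = float("inf")
                call = "introgressed" if cx >= min_target_cov else "unresolved"
            else:
                ratio = cx / co
                call = "introgressed" if ratio >= ratio_min else "native"
            bins.append(
                IntrogressionBin(subgenome.assembly_id, chrom, s, e,
                                 float(co), float(cx), ratio, call,
                                 terminal, zero_den)
            )
    return bins


def bin_table(bins: list[IntrogressionBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(subgenome=b.subgenome, chrom=b.chromosome, start=b.start,
                 end=b.end, cov_own=round(b.cov_own, 4),
                 cov_other=round(b.cov_other, 4),
                 ratio=b.ratio, call=b.call, terminal=b.terminal)
            for b in bins
        ]
    )


def introgression_summary(bins: list[IntrogressionBin]) -> pd.DataFrame:
    """Per-chromosome introgressed megabases (sum of introgressed bins)."""
    df = bin_table(bins)
    hit = df[df["call"] == "introgressed"]
    if hit.empty:
        return pd.DataFrame(columns=["chrom", "n_bins", "introgressed_mb"])
    g = hit.assign(length=hit["end"] - hit["start"]).groupby(
        "chrom", as_index=False
    ).agg(n_bins=("chrom", "size"), introgressed_bp=("length", "sum"))
    g["introgressed_mb"] = g.pop("introgressed_bp") / 1e6
    return g


def density_track(bins: list[IntrogressionBin], window: int = 1_000_000
                  ) -> pd.DataFrame:
    """Introgressed-bin density per genomic window (for plotting)."""
    df = bin_table(bins)
    df["win"] = df["start"] // window
    g = df.groupby(["chrom", "win"], as_index=False).agg(
        n_bins=("call", "size"),
        n_introgressed=("call", lambda c: int((c == "introgressed").sum())),
    )
    g["start"] = g.pop("win") * window
    g["density"] = g["n_introgressed"] / g["n_bins"]
    return g[["chrom", "start", "n_bins", "n_introgressed", "density"]]
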