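"""Domain types and readers/writers for the external formats the pipeline touches.

Conventions
-----------
Every coordinate in an external file (FASTA indexes aside) is 1-based and
inclusive, as in show-coords/VCF/GFF3.  Every coordinate held in memory is
0-based, half-open.  Conversion happens here, at the I/O boundary, and
nowhere else.  Reverse-orientation alignment blocks always store ascending
coordinates plus an orientation flag, never descending coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("polysv")

VALID_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violated the contract of its format."""


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------


@dataclass
class GenomeSet:
    """A named assembly: chromosome name -> uppercase DNA string."""

    assembly_id: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise FormatError(
                    f"{self.assembly_id}/{name}: invalid characters {sorted(bad)!r}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


def read_genome(path: str | Path, assembly_id: str | None = None) -> GenomeSet:
    """Read a FASTA file into a :class:`GenomeSet` (lowercase folded to upper).

    Duplicate record names and empty files are hard errors.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise FormatError(f"{path}: no FASTA records")
    return GenomeSet(assembly_id or path.stem, sequences)


def write_genome(genome: GenomeSet, path: str | Path, width: int = 80) -> None:
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """One gene locus: sorted exon and CDS intervals on a chromosome.

    Intervals are 0-based half-open and non-overlapping; the CDS is contained
    in the exon union and its total length is at least one codon.
    """

    gene_id: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                if c < b:
                    raise FormatError(f"{self.gene_id}: overlapping {name}")
            if any(a >= b for a, b in ivs):
                raise FormatError(f"{self.gene_id}: empty {name} interval")
        if self.cds_length < 3:
            raise FormatError(f"{self.gene_id}: CDS shorter than one codon")
        for a, b in self.cds:
            if not any(ea <= a and b <= eb for ea, eb in self.exons):
                raise FormatError(f"{self.gene_id}: CDS interval outside exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(b, c) for (_, b), (c, _) in zip(self.exons, self.exons[1:])]

    def spliced_cds(self, genome: GenomeSet) -> str:
        """Coding sequence on the coding strand."""
        from ._dna import revcomp

        s = "".join(genome.fetch(self.chromosome, a, b) for a, b in self.cds)
        return revcomp(s) if self.strand == "-" else s


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features from a GFF3 file.

    When a gene carries several mRNAs the one with the longest CDS is kept
    (the conventional 'longest transcript' choice for ortholog comparison).
    Other feature types are ignored.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        best: GeneModel | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
            if not cds:
                continue
            model = GeneModel(gene.id, gene.seqid, gene.strand, exons or cds, cds)
            if best is None or model.cds_length > best.cds_length:
                best = model
        if best is not None:
            models[gene.id] = best
    return sorted(models.values(), key=lambda g: (g.chromosome, g.span))


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.span)):
            s, e = g.span
            row = [g.chromosome, "polysv", "gene", str(s + 1), str(e), ".", g.strand, "."]
            fh.write("\t".join(row + [f"ID={g.gene_id}"]) + "\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(
                "\t".join(row[:2] + ["mRNA", str(s + 1), str(e), ".", g.strand, "."])
                + f"\tID={mrna};Parent={g.gene_id}\n"
            )
            for a, b in g.exons:
                fh.write(
                    f"{g.chromosome}\tpolysv\texon\t{a + 1}\t{b}\t.\t{g.strand}\t."
                    f"\tParent={mrna}\n"
                )
            for a, b in g.cds:
                fh.write(
                    f"{g.chromosome}\tpolysv\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t0"
                    f"\tParent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# alignment blocks
# ---------------------------------------------------------------------------


@dataclass
class AlignmentBlock:
    """A chained collinear match between two genomes.

    ``ops`` is an optional gapped base-level alignment as a list of
    ``(op, length)`` runs with op one of ``=`` (match), ``X`` (mismatch),
    ``I`` (insertion in the query), ``D`` (deletion from the query).  The
    alignment relates ``ref[ref_start:ref_end]`` to the query span taken on
    the forward strand for ``+`` blocks and reverse-complemented for ``-``.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    qry_chrom: str
    qry_start: int
    qry_end: int
    orientation: str = "+"
    identity: float = 1.0
    ops: list[tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end or self.qry_start >= self.qry_end:
            raise ValueError("alignment block spans must be non-empty and ascending")
        if self.orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")
        if self.ops is not None:
            rlen = sum(n for op, n in self.ops if op in "=XD")
            qlen = sum(n for op, n in self.ops if op in "=XI")
            if rlen != self.ref_len or qlen != self.qry_len:
                raise ValueError("base alignment lengths disagree with spans")

    @property
    def ref_len(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def qry_len(self) -> int:
        return self.qry_end - self.qry_start

    @property
    def score(self) -> float:
        """Weight used by the one-to-one / global filters."""
        return self.ref_len * self.identity


def read_alignment_table(path: str | Path) -> list[AlignmentBlock]:
    """Read alignment blocks from a show-coords-style table or a PAF file.

    The coords dialect is the 13-column tab-separated form produced by
    ``show-coords -rclTH``: S1 E1 S2 E2 LEN1 LEN2 %IDY LENR LENQ COVR COVQ
    ref qry, with 1-based inclusive coordinates and reverse hits written with
    descending query coordinates.  PAF is detected by its +/- strand in
    column 5; PAF target coordinates are taken as the reference side.
    Rows with out-of-range coordinates are rejected with a warning.
    """
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if len(f) >= 12 and f[4] in "+-":
                    blk = _parse_paf_row(f)
                elif len(f) == 13:
                    blk = _parse_coords_row(f)
                else:
                    raise FormatError(f"unrecognized column count {len(f)}")
            except (FormatError, ValueError) as exc:
                log.warning("%s:%d: rejected row (%s)", path, lineno, exc)
                continue
            blocks.append(blk)
    return blocks


def _parse_coords_row(f: list[str]) -> AlignmentBlock:
    s1, e1, s2, e2 = (int(x) for x in f[:4])
    idy = float(f[6]) / 100.0
    ref, qry = f[11], f[12]
    if s1 > e1:
        raise FormatError("descending reference coordinates")
    orientation = "+"
    if s2 > e2:
        orientation = "-"
        s2, e2 = e2, s2
    if min(s1, s2) < 1:
        raise FormatError("coordinates must be >= 1")
    return AlignmentBlock(ref, s1 - 1, e1, qry, s2 - 1, e2, orientation, idy)


def _parse_paf_row(f: list[str]) -> AlignmentBlock:
    qry, qlen, qs, qe = f[0], int(f[1]), int(f[2]), int(f[3])
    ref, rlen, rs, re_ = f[5], int(f[6]), int(f[7]), int(f[8])
    nmatch, alnlen = int(f[9]), int(f[10])
    if qs < 0 or rs < 0 or qe > qlen or re_ > rlen:
        raise FormatError("coordinates out of range")
    idy = nmatch / alnlen if alnlen else 0.0
    return AlignmentBlock(ref, rs, re_, qry, qs, qe, f[4], min(idy, 1.0))


def write_alignment_table(blocks: Iterable[AlignmentBlock], path: str | Path,
                          ref_lengths: dict[str, int] | None = None,
                          qry_lengths: dict[str, int] | None = None) -> None:
    """Write blocks in the 13-column coords dialect (1-based inclusive)."""
    with open(path, "w") as fh:
        for b in blocks:
            s2, e2 = b.qry_start + 1, b.qry_end
            if b.orientation == "-":
                s2, e2 = e2, s2
            lenr = (ref_lengths or {}).get(b.ref_chrom, 0)
            lenq = (qry_lengths or {}).get(b.qry_chrom, 0)
            covr = 100.0 * b.ref_len / lenr if lenr else 0.0
            covq = 100.0 * b.qry_len / lenq if lenq else 0.0
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.ref_start + 1, b.ref_end, s2, e2,
                        b.ref_len, b.qry_len, f"{100.0 * b.identity:.2f}",
                        lenr, lenq, f"{covr:.2f}", f"{covq:.2f}",
                        b.ref_chrom, b.qry_chrom,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED / VCF / config
# ---------------------------------------------------------------------------


def write_bed(records: Iterable[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name[, score]]) tuples as BED."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), *f[3:]))
    return out


def write_vcf(variants, contigs: dict[str, int], path: str | Path,
              sample_genotypes: "np.ndarray | None" = None,
              samples: Sequence[str] | None = None) -> None:
    """Write variant records as VCF v4.2.

    ``variants`` supplies objects with ``ref_chrom``/``ref_pos`` (0-based) and
    ``ref_allele``/``alt_allele`` attributes, or plain tuples
    ``(chrom, pos, ref, alt)``.  Positions are sorted per chromosome on
    output.  An optional accession x site genotype matrix (codes 0/1/2,
    -1 = missing) adds GT columns.
    """
    rows = []
    for i, v in enumerate(variants):
        if isinstance(v, tuple):
            chrom, pos, ref, alt = v[:4]
        else:
            chrom, pos, ref, alt = v.ref_chrom, v.ref_pos, v.ref_allele, v.alt_allele
        rows.append((chrom, pos, ref, alt, i))
    order = sorted(range(len(rows)), key=lambda j: (rows[j][0], rows[j][1]))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=polysv\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if sample_genotypes is not None:
            header += "\tFORMAT\t" + "\t".join(samples or [])
        fh.write(header + "\n")
        for j in order:
            chrom, pos, ref, alt, i = rows[j]
            line = f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t."
            if sample_genotypes is not None:
                gts = "\t".join(gt_map[int(g)] for g in sample_genotypes[:, i])
                line += "\tGT\t" + gts
            fh.write(line + "\n")


def lint_vcf(path: str | Path) -> list[str]:
    """Syntactic VCF check: header present, ploidy-consistent columns,
    positions sorted per chromosome.  Returns a list of problems (empty if
    the file passes)."""
    problems: list[str] = []
    last: dict[str, int] = {}
    saw_header = saw_columns = False
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##"):
                saw_header = saw_header or line.startswith("##fileformat=VCF")
                continue
            if line.startswith("#CHROM"):
                saw_columns = True
                ncols = len(line.split("\t"))
                continue
            f = line.split("\t")
            if ncols is not None and len(f) != ncols:
                problems.append(f"line {lineno}: column count {len(f)} != {ncols}")
            chrom, pos = f[0], int(f[1])
            if pos < last.get(chrom, 0):
                problems.append(f"line {lineno}: unsorted position {chrom}:{pos}")
            last[chrom] = pos
    if not saw_header:
        problems.insert(0, "missing ##fileformat header")
    if not saw_columns:
        problems.insert(0, "missing #CHROM column line")
    return problems


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` run configuration."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"config line without '=': {line!r}")
            key, val = line.split("=", 1)
            cfg[key.strip()] = val.strip()
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, val in cfg.items():
            fh.write(f"{key} = {val}\n")
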