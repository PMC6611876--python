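# Methods

This note records the models, parameter choices and numerical conventions
behind `polysv`, including the points where the design was genuinely open
and what the synthetic benchmarks do and do not demonstrate.

## Coordinates and formats

All in-memory coordinates are 0-based half-open; all file coordinates
(coords tables, GFF3, VCF) are 1-based inclusive, converted only at the I/O
boundary.  Reverse-orientation alignment blocks always store ascending
coordinates plus an orientation flag; the coords dialect writes them with
descending query coordinates, as show-coords does.  A consequence of that
convention is that a 1-bp reverse hit is unrepresentable in the file format
(start equals end), which the round-trip property test documents by
excluding length-1 blocks.

The coords reader accepts the 13-column `show-coords -rclTH` layout
(S1 E1 S2 E2 LEN1 LEN2 %IDY LENR LENQ COVR COVQ ref qry) and PAF
(detected by the `+`/`-` strand in column 5; the PAF target is taken as the
reference side).  Which column set the original workflow used is not
knowable from the outside, so both are supported and the mapping is fixed
here.

## Whole-genome alignment

Anchors are k-mers (default k = 21, a free parameter in the 15–31 range)
that occur exactly once in the reference, matched on both strands and
collapsed along diagonals into maximal exact matches.  Unique seeding
suppresses repeat noise without a repeat masker; this is adequate for the
mostly unique synthetic genomes, and real repeat-dense assemblies are
expected to enter through imported nucmer/minimap2 tables instead.  Greedy
chaining joins anchors whose gaps on both genomes are ≤ `max_anchor_gap`
(default 2,000 bp) with consistent orientation; inter-anchor gaps are
closed by global base-level alignment (edlib's edit-distance-optimal path,
which coincides with a +1/−1/−2 scoring optimum for the near-identical gap
sequences this sees).  Chains shorter than `min_block` (500 bp) are
dropped.  Block identity is defined as the match-column fraction of the
block's own base alignment, so it is self-consistent by construction.

`min_anchor` optionally discards maximal exact matches shorter than a
given length before chaining.  The introgression scanner sets it to 50 bp
to emulate a word-size-50 local search: at ~10% divergence, exact runs of
50 bp are vanishingly rare, so chains cannot crawl across highly diverged
sequence, while ~2%-diverged sequence still seeds densely.

The two filters both tolerate up to 50 bp of overlap between retained
blocks, because maximal exact anchors can extend a few bases past a
rearrangement junction (the junction base happens to match both contexts);
without the tolerance, a 2-bp junction overlap would force one of two
large, correct blocks out of the solution.

Tie-breaks in the weighted scheduling prefer the longer block, then the
smaller reference start, making output deterministic.

## SV classification

A one-to-one block is *allelic* when ≥ 50% of its reference span is covered
by the global collinear chain and its orientation is forward.  The 50%
majority rule resolves an ambiguity in the recipe (whether blocks partially
overlapping the chain count as translocated); a block must be
majority-supported by the collinear backbone to be allelic.  Non-allelic
blocks are typed by context: a query chromosome different from where the
flanking allelic blocks map ⇒ inter-chromosomal translocation; reverse
orientation in the right chromosome context ⇒ inversion; otherwise (right
chromosome, forward strand, order-inconsistent placement) ⇒
intra-chromosomal translocation.  Blocks with no allelic neighbour fall
back to the chromosome-level majority pairing and are flagged
low-confidence.  Reciprocal translocations are reported as two
inter-translocation records; pairing them is left to reporting.

Same-kind regions on the same chromosome pair are merged when both the
reference and the query gap are ≤ `join_gap`.  The default of 50 kb is this
package's own choice — the merging step it models was done manually in the
workflow it mirrors — and the region count is monotonically non-increasing
in `join_gap`, which the tests assert.

## Variant calling and buffering

SNPs and single-base indels are read from alignment columns of allelic
blocks; `Buffering` (default 20 bp) is interpreted as the minimum distance
to the nearest other variant *or block edge*, mirroring the BUFF column
semantics of standard whole-genome-aligner SNP output.  Indels of 2–100 bp
are emitted both from within-block gap runs (the chainer absorbs events
shorter than `max_anchor_gap` into blocks) and from gap-length differences
between mutually consistent adjacent allelic blocks; events longer than
100 bp are left to the PAV caller.  Indels are reported VCF-style, anchored
on the preceding reference base.

## PAV calling

Unaligned regions are the complement of all one-to-one block spans on the
carrier genome, plus carrier-only gap runs longer than 100 bp inside
blocks.  Categories follow the show-diff vocabulary with decision order
GAP → INV → SEQ → JMP → DUP → BRK (specific before generic); DUP requires
the flanking counterpart interval to re-use already-aligned sequence
(counterpart gap < −50 bp, the same junction tolerance as the filters).
The >100 bp length floor is applied before the uniqueness filter.  The
uniqueness filter aligns each region to the *counterpart* genome — a
presence region unique to one cultivar must be absent from the other; the
recipe's "aligned to their respective genome" is ambiguous on this point
and the counterpart reading is implemented — and rejects regions with
coverage > 50% and identity > 90%.  Coverage is the aligned-base fraction
of the region (union over hits).  PAV genes require ≥ 80% of CDS length
inside retained regions; that threshold is this package's own definition,
configurable, since no membership rule is stated anywhere.

## Introgression

Each 5-kb bin of a subgenome is scored by its aligned-base coverage
against both ancestors (blocks at ≥ 90% identity, seeds and blocks
≥ 50 bp).  Bins under 70% coverage in both ancestors are unresolved;
otherwise a bin is introgressed when cov_other/cov_own ≥ 1.5, including
the degenerate cov_own = 0 case with cov_other ≥ 0.7 (a zero denominator
is the strongest possible signal; it carries a distinct flag).  Whether
the original ratio used alignment length, bit score or target-fraction is
unspecified; alignment-length coverage is implemented.  Terminal short
bins are scored but flagged.

## Gene-pair taxonomy

The longest transcript represents each gene; the genic region ± 2 kb is
aligned globally and variants are assigned to upstream/downstream flank,
UTR, CDS and intron sub-regions.  Frame judgement uses the net CDS indel
length (the optimal base alignment may split one biological indel into
adjacent gap pieces, and compensating indels restore frame): net ≡ 0 mod 3
is an in-frame indel, compatible with structural conservation ("deletion
of some codons"); otherwise a frameshift.  Start-codon loss, premature or
lost stops (one label covering both directions), and GT/AG splice-site
changes are large-effect; unequal exon counts or a CDS segment ≥ 80%
gapped in the counterpart are large structural variation.  Non-canonical
reference introns are flagged rather than classified, and reference genes
with internal stops are excluded from tabulation.  Category precedence is
structural > large-effect > conserved, so the three categories partition
every classified pair.  The report offers both the nested count/percent
table (percentages of the column total at two decimals) and a flat
per-effect view, because the nested sub-rows of the table it mirrors do
not obviously sum.

## Population genetics

Accessions are treated as highly inbred: genotypes are alt-dosage 0/1/2
(het kept as dosage 1), allele frequencies use dosage/2, and the allele
sample size per site is the number of called accessions.  Per-site π is
the unbiased heterozygosity 2p̂q̂·n/(n−1); window values divide the site sum
by the window length.  F_ST is the Weir–Cockerham (1984) weighted
estimator, Σa/Σ(a+b+c) over window sites (the package the recipe names
does not pin an estimator; Weir–Cockerham is the field default).
Haplotype diversity is (n/(n−1))(1−Σfᵢ²) over clusters of identical
genotype vectors in 10-kb tiles — the concrete form chosen here for a
definition cited only indirectly — with missing calls making an accession
its own cluster, and tile values averaged in 1-Mb windows.  Private vs
common SNPs are counted after down-sampling the larger group to the
smaller's size, a site carrying the SNP in a group when any called
accession holds the alternate allele.  The NJ two-way cut is the
bipartition under the tree's longest internal branch (the visual
two-cluster cut made operational).  Breakpoint genotyping counts a
spanning mate pair as reference-like when the mates point inward within
mean ± 4 sd, and alternate-like on same-strand or out-of-range anomalies;
calls require unanimous evidence with ≥ 2 spanning pairs (conservative,
hence an explicit unassigned class), and per-SV calls are reported
separately plus a combined call that goes unassigned on any contradiction.
Recombination windows pro-rate inter-bin cM linearly; map density is total
cM over bin count.

## The synthetic generators

The generators define the study conditions and are not tuned per run:

- `simulate_genome_pair` derives genome B from A by applying requested
  inversions (reverse complement in place), translocations and PAV events
  through an exact piece table, then planting SNPs and 1–10 bp indels
  (uniform length, matching a 1-bp-dominant indel spectrum, simply) at the
  requested per-bp rates.  Planted variants fall only outside engineered
  spans, at least 100 bp from any junction and spaced ≥ 13 bp apart, so
  every one is recoverable by alignment and no two collide; truth records
  exact 0-based breakpoints on both genomes.  PAV inserts are random DNA
  at 40% GC (no TE library needed).
- `simulate_introgression_trio` builds two ancestors at 5% divergence each
  from a common base (~10% apart — the order of magnitude separating the
  two cotton diploid ancestors) and a subgenome at 2% from its own
  ancestor, with swap spans copied from the other ancestor.
- `simulate_panel` defaults to the 66/348 reference-like/alternate-like
  split of the panel it emulates, 20,000 sites on a 30-Mb chromosome with
  an 8-Mb inversion (desk-scale stand-ins for the genome-wide panel).
  Outside the inversion all accessions draw from one frequency vector;
  inside, 60% of sites are haplotype-structured (half fixed differences,
  half single-group polymorphisms) and within-group minor-allele
  frequencies are scaled by 0.2, emulating a non-recombining haplotype.
  Small het (1%) and missing (2%) rates add realistic noise.
- `simulate_mate_pairs` works at coordinate level: fragments drawn around
  each junction on the chosen haplotype, mapped back through the inversion
  transform (mirror + strand flip inside the span); reads straddling a
  junction are dropped, as split alignments would be.
- `simulate_ril_map` integrates a piecewise-constant cM/Mb rate over
  evenly spaced bins, scaling increments inside the suppressed span.

One integer seed feeds a named substream per generator, so outputs are
byte-identical across runs and stable under call reordering.

## What the benchmarks show — and what they do not

The test suite and the acceptance script run the pipeline on 10-Mb-scale
genomes at 1% SNP divergence with six engineered rearrangements, 1–3 kb
PAV events, 50–60 kb introgression swaps, and the default panel; these
sizes keep a full run on one CPU in minutes while leaving every detection
threshold far from its breaking point.  Passing them demonstrates internal
correctness — recovery of known truth, agreement with closed forms and
brute-force oracles — not performance on real 2.3-Gb repeat-rich
assemblies, where alignment would come from a dedicated aligner via the
import path and repeat handling, scaffold errors and missing data dominate
the difficulty.  Genome-scale published counts (SNP totals, rearranged Mb,
the real panel split) are inputs to the reporting arithmetic only; they
are not desk-reproducible and are not claimed by any test.

## Known limitations

- The aligner is a desk-scale tool: no affine gaps, no vectorised DP, no
  repeat masking beyond unique seeding.
- PAV ancestral-ortholog tracing, phylogenetic introgression tests,
  bootstrap support values and PCA are out of scope.
- Ortholog pairing is an input (truth pairing or a user list), not
  inferred.
- Full-length LTR discovery is upstream of the dating module, which
  consumes LTR or copy/consensus pairs as given.
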