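# Methods

This note documents the models, parameter choices and numerical
conventions behind `tetrasnp`, and what the synthetic data do and do not
establish about real transcriptome SNP discovery.

## The synthetic tetraploid dataset

The generator emulates a two-genotype cDNA pyrosequencing experiment in an
autotetraploid outcrosser. Reference transcripts (loci) are i.i.d. uniform
ACGT sequences, lengths uniform over `locus_length_range`
(default 300–2000 bp). Each genotype carries exactly four haplotypes per
locus; variation is planted per position, independently across positions:

* with probability `between_div_rate` (default 0.001/bp) the second
  genotype's background allele becomes one of the three other bases —
  a fixed inter-genotype difference;
* independently, with probability `within_het_rate` (default 0.002/bp)
  per genotype, that genotype is heterozygous at the site: a second allele
  (uniform over the three bases other than its background) is placed on
  *d* of its four haplotypes, with dosage *d* ∈ {1, 2, 3}
  (simplex/duplex/triplex) drawn from `dosage_weights`
  (default 0.5/0.3/0.2 — tetrasomic inheritance admits all three and the
  source protocol gives no dosage spectrum, so simplex-skewed weights were
  fixed once as the generic heterozygous-outcrosser expectation).

Planted variants are substitutions only; indels enter exclusively as
sequencing errors, because the discovery target is base substitutions and
indel-like variation in this read chemistry is dominated by homopolymer
miscalls. Every planted site is written to a truth table with per-genotype
allele dosages, per-haplotype alleles, and the category the classifier
must assign (computed with the same classifier, so truth and pipeline can
never drift apart definitionally; an independent restatement of the rules
guards the classifier itself in the tests).

Reads are single-pass and strand-symmetric, uniform over the four
haplotypes. Read counts per locus and genotype are Poisson with mean
`depth_per_genotype` (default 10 — "depth" here is reads per locus, not
per-base coverage; with ~380 bp reads on ~1.2 kb loci it corresponds to
roughly 3x per-site coverage per genotype). Lengths follow a clipped
normal (min 100, max 636, mean 379, sd 60 bp), matching the read-length
envelope of half-plate Titanium runs after sub-100 bp trimming. Errors:

* substitutions i.i.d. per base at `sub_error_rate` (default 0.001);
* per homopolymer run of length ≥ 2, with probability
  `homopolymer_indel_rate` (default 0.02) one repeat unit is inserted or
  deleted (equal odds) — the characteristic flowgram error mode.

No base qualities, no chimeras/paralogs (a paralog-mixture fixture is
built directly in the confidence tests), and no expression heterogeneity
beyond Poisson depth: preferential allele expression or allele silencing
in pooled cDNA is *not* modeled. Passing tests therefore demonstrate
correctness of the calling/classification machinery under known truth,
not robustness to allelic expression bias or library artifacts.

One seeded generator (`numpy` PCG64) drives transcripts, variants and
reads in a fixed stage order, so a config (including its seed) reproduces
every artifact byte for byte.

## Contig alignments

Assembly itself is out of scope; contigs come from truth placements
(simulation), from external ACE files, or from placements refined with a
semi-global pairwise aligner (read fully aligned, free end gaps on the
target; affine scores, default match +1 / mismatch −1 / gap open −2 /
extend −1; Biopython's `PairwiseAligner` provides the DP). Reads whose
recorded span equals their length are placed directly; indel-bearing reads
are realigned against the reference backbone within a ±16 bp window, and
their insertions open pad columns (left-aligned within the insertion
slot). Reverse-strand reads are stored reverse-complemented with the
orientation flag, following assembly-viewer convention.

Consensus is a per-column majority over all reads, both genotypes pooled.
Ties between bases break alphabetically (A < C < G < T); a pad wins only
with a strict majority (gap loses ties to bases); uncovered columns are
`N`. Coordinates are 0-based half-open internally and 1-based in ACE and
all reports.

The ACE writer emits the consed dialect (CO/BQ/AF/RD/QA/DS; `*` pads). A
constant placeholder consensus quality is written because qualities are
not modeled but standard consumers require the BQ segment. The reader is
this package's own (it reports parse errors with line numbers and carries
the genotype tag through the DS line); an independent ACE implementation
cross-checks the writer in the tests.

## Candidate SNP calling

Per column and genotype the caller counts A/C/G/T and gap observations
among covering reads (case-insensitive). The rules, in order:

1. alleles with fewer than `min_reads_per_allele` (default 2) supporting
   reads within their genotype are dropped; gaps are never alleles;
2. a column is a candidate iff ≥ 2 distinct alleles remain pooled across
   genotypes;
3. candidates at pad-consensus columns are voided
   (`filtered_indel_column`);
4. with `require_both_genotypes_covered` (default on), a candidate where
   either genotype has fewer than `min_reads_per_allele` *base*
   observations is voided (`filtered_uncovered`). Base observations
   rather than covering reads are counted so that gap-only coverage does
   not legitimize a between-genotype call — the point of the toggle is to
   avoid phantom Category 1/2 calls from one-sided coverage;
5. the confidence score is the percentage of read bases matching the
   consensus over up to 10 non-pad consensus columns on each side of the
   candidate (the column itself excluded; truncated silently at contig
   ends; gaps excluded from numerator and denominator; pooled over all
   reads — the window width and the pooled-versus-per-read choice are
   this package's, the source procedure being verbal on both). Calls
   below `min_confidence` (default 90.0) are voided; exactly 90.0 is
   retained, reading the exclusion as strictly-below;
6. no record is emitted for monomorphic or gap-only-variation columns.

Remap QC serializes the contig through the ACE writer/reader and
re-extracts every supporting read's base at the call column; the call is
flagged good only if the per-genotype allele counts reproduce exactly.

Category is computed from the support-filtered allele sets (the catalog
describes final candidates, not raw observations). Reported positions are
1-based on the unpadded consensus.

## Anchoring and catalog summaries

PSL identity is the pure match ratio
`(matches + repMatches) / (matches + repMatches + misMatches)` — N bases
and query gaps excluded; web-BLAT "percent identity" differs, so the
formula is documented and the coverage basis is configurable. Coverage
defaults to the aligned query span `(qEnd − qStart)/qSize` (the common
reading of "coverage"; summed block lengths are available via
`coverage_mode="blocks"`). Both thresholds (defaults 95% identity, 90%
coverage) are inclusive: "threshold of X" reads as ≥ X. `keep-all` is the
default best-hit policy for chromosome tallies (every mapped contig
counts); `keep-best` (most matching bases, ties by identity, then target
name, then start) serves downstream single-placement uses. Target names
not matching `chr<number>` pool into the catch-all `Chr0` bucket.
Category percentages are printed to one decimal, rounding half away from
zero. Length reports bin reads in 100 bp closed-open steps and assembled
sequences in 100–500 / 501–1000 / 1001–1500 / 1501–2000 / >2000 bp bins,
as the conventional pre/post-assembly presentation implies.

## Assay design

Melting temperatures use the unified nearest-neighbor parameters
(Allawi & SantaLucia 1997) with the SantaLucia 1998 entropy salt
correction at fixed conditions — 50 mM monovalent cation, 50 nM primer,
template in excess — chosen once to sit on the scale of standard primer
design defaults; the model is deterministic and symmetric under reverse
complement. Design enumerates amplicons smallest-first (small amplicons
are the preferred melting-assay format), leftmost placement and shortest
primers as tie-breaks, requiring both primers inside the amplicon, off
the SNP base, within length 18–24 bp and Tm 59–61 °C, amplicon 40–200 bp,
and at most `max_other_variants_in_amplicon` (default 0) other known
variant columns inside the amplicon — extra variants distort melt
profiles, which is precisely the dominant failure mode of melting-curve
validation. Each emitted target carries a categorical expected melt
class (two distinct homoduplex peaks for fixed differences; het-vs-hom
peak contrast otherwise); no quantitative melting-curve simulation is
attempted. SNPs without a feasible design are reported with a reason
(insufficient flank, Tm infeasible, or co-located variants).

## Pipeline and reproducibility

Stages run in a fixed order (simulate, call, classify, anchor, design,
report); each reads only declared inputs, writes TSV/FASTA/ACE artifacts,
and leaves a `<stage>.partial` marker if it fails. A manifest records the
config snapshot, per-stage wall time and SHA-256 digests of every output;
identical configs reproduce identical digests. Anchoring always consumes
a provided PSL file — the pipeline does not fabricate genome alignments.

## Problem sizes in the test suite

The suite validates recovery at 200 loci × mean 10 reads/locus/genotype
(error-free exactness), 200 loci at depth 3 (support-threshold
accounting), 60 loci of indel-only errors, and ~1 Mb of transcriptome
(870 loci) for category-frequency recovery against the exact site-state
enumeration; the frequency check is run error-free because it targets the
variant-rate model, while error behavior is covered by the dedicated
depth and indel suites. At roughly 3x per-site coverage per genotype,
allele dropout — not sequencing error — dominates the difference between
planted and called category proportions, so frequency comparisons are
made on the truth table and on the fully supported called subset, where
agreement must be exact.

## Known limitations

* No de novo assembly: contig structure comes from placements or external
  ACE files; misassembly is only probed via constructed fixtures.
* The confidence score is pooled over reads; a per-read variant could
  behave differently on highly uneven coverage.
* Dosage is planted but not estimated; the caller reports allele sets,
  not genotypes with dosage likelihoods.
* Intron structure is invisible to cDNA-based design: a primer pair
  spanning an intron would fail on genomic DNA, and this cannot be
  modeled without a genome.
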