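# Methods

## Coordinate model

Every in-memory interval is 0-based, half-open `[start, end)` on a named
contig, optionally stranded. Readers convert at the file boundary and
nowhere else: BED and bedGraph are already half-open (offset 0); GFF3 and
VCF are 1-based inclusive (−1 on the start only); printed supercontig
ranges of the form `Supercont1.N:start–end` are treated as 1-based
inclusive, which is the convention genome browsers print for
scaffold-based assemblies. That assumption is isolated in
`parse_printed_range` so it can be revisited without touching any
analysis code. Contig names are matched exactly; no `chr`-prefix
normalization is attempted because scaffold assemblies do not use it.

A gene model carries its biotype, stranded span, exons, and UTR spans.
The TSS is defined structurally: the first base of a + strand gene, the
last base of a − strand gene. Gene-level models are used throughout;
transcript isoforms are deliberately out of scope.

## Peak classification

A peak relates to a gene in one or more of these ways:

* **exonic** — the peak lies fully inside one exon;
* **intronic** — fully inside one intron;
* **exon_intron_boundary** — the peak covers bases on both sides of at
  least one splice junction. These three are mutually exclusive per
  (peak, gene) pair, and "intragenic" is their union: a peak that merely
  straddles a gene edge is not inside the gene and receives none of them.
* **upstream_1kb** — the peak does not touch the gene body and its
  nearest edge is within `window_upstream` (default 1000 bp) of the TSS
  on the strand-appropriate side. For non-coding genes the peak is
  additionally **ncRNA_upstream_1kb**.
* **proximal_promoter** — the peak overlaps the promoter window, by
  default 250 bp upstream through 50 bp downstream of the TSS. There is
  no universal definition of "proximal promoter"; this window is a common
  convention and both margins are parameters.
* **five_utr / three_utr** — the peak overlaps a UTR span of the gene
  (additive to the categories above).
* **intergenic** — no relation to any gene; exclusive of everything else.

Signed TSS distance is 0 when the peak contains the TSS, otherwise the
base-to-base gap to the nearest peak edge, negative upstream. Ties
between equidistant TSSs break to the lexicographically smaller gene id
for determinism. A peak may carry categories from different genes
simultaneously (intronic in gene A, upstream of gene B); summary tables
count each peak once per category and also report the number of distinct
genes behind each category, since peak counts and gene counts differ.

The classifier is exercised against an independent per-base brute-force
implementation on hundreds of unstructured random instances; the two must
agree exactly.

## TSS metagene profile

For each TSS, signal is sampled over `[-window, +window)` (default ±1000
bp), mirrored for − strand genes so upstream is always negative, then
averaged within uniform bins (default 25 bp, resolving a 100 bp feature
with four bins). The default signal is 0/1 peak coverage; a bedGraph
track can be supplied for read-depth-like signal. TSSs closer than the
window to a contig edge contribute only their in-range bases. The profile
peak offset is the center of the maximum bin, ties broken toward 0, with
a sentinel for flat profiles.

One geometric caveat drove a design choice: with ~550 bp peaks lying
fully upstream of TSSs, indicator coverage cannot peak narrowly at
100–200 bp upstream (a 550 bp box whose near edge is at 100–200 bp
necessarily also covers 200–650 bp). A sharp 100–200 bp upstream maximum
is a property of read signal around promoter-proximal peaks that straddle
the TSS. The synthetic generator therefore emits a read-depth-like
bedGraph (a low plateau over every peak plus a tall summit bump over
TSS-proximal peaks) and the profile-recovery tests use that source, while
narrow-peak indicator coverage is covered by unit tests.

## Expression association

Genes are flagged expressed when abundance exceeds a threshold (default
0; the source study does not state its expressed-gene definition, so the
threshold is exposed). A gene is peak-associated when at least one peak
is within 1 kb upstream or intragenic. The upstream/intragenic split
counts a gene with both kinds of peak as upstream, making the split
exhaustive and mutually exclusive. The positional-effect statistic is the
ratio of arithmetic mean abundance between genes whose nearest upstream
peak is ≤ `near` bp (default 100) from the TSS and genes whose nearest
upstream peak falls in `(near, window]`; a log-abundance variant is
available, and the comparison conditions on expressed genes by default.
Empty comparison groups yield a flagged sentinel rather than a number.

## SNP mapping and the resampling null

A SNP maps to every peak whose interval contains its position. Distinct
SNPs inside at least one peak are counted once for the genome-wide rate;
a SNP inside two overlapping peaks contributes to both peaks' counts,
because the peak is the resampling unit. Each bootstrap replicate draws a
fixed number of peaks uniformly — without replacement by default, since
peaks are a finite population; with-replacement sampling is available and
has the same expectation — and sums their SNP counts. The headline
statistic is 1000 × mean(replicate count)/sample size, which converges to
1000 × (SNPs in peaks)/(total peaks).

The assortment-bias test compares an observed SNP count (scaled linearly
to the replicate sample size if it covers a different number of peaks)
against the replicate distribution with a two-sided add-one empirical
p-value; "no bias" is flagged at p > 0.05, and a zero-variance null
yields a sentinel. Calibration was checked by simulating datasets under
the null and testing the p-value distribution for uniformity
(Kolmogorov–Smirnov at α = 0.01, 200 datasets). Because the replicate
count is integer-valued, the empirical p is conservative when replicate
counts are sparse (a property of any discrete test statistic); the
calibration experiments use SNP densities high enough (~150 SNPs per
replicate) that the statistic is effectively continuous.

## Motif enrichment

PWMs are normalized with a pseudocount of 1 % of each position's total
(avoiding −∞ log-odds) and scored as log₂(P_pwm/P_background) summed over
each window, both strands, windows containing N skipped. A window
scoring at least the bit threshold — default 6, interpreted as a per-hit
log-odds cutoff and exposed in configuration — is a hit, and the hit
count is the motif's incidence. The raw enrichment score is incidence per
kilobase scanned; the p-value is add-one empirical against `n_sets`
resampled background sets (so finite resampling never reports p = 0),
deterministic given a seed. Backgrounds are either length-matched windows
drawn from non-peak genome sequence or exact dinucleotide shuffles of the
peak sequences (random Eulerian walk on the dinucleotide graph). Outputs
are labelled Clover-style: the incidence/threshold/p-value semantics
follow the Clover analysis pattern, but no attempt is made to replicate
Clover's internal raw score.

## UTR elements

Detection runs on mRNA-sense UTR sequences (minus-strand genes are
reverse-complemented at extraction). A uORF is any ATG in the 5' UTR with
an in-frame stop codon downstream within the UTR, at least 2 codons long
including the stop (the minimum is a parameter; the upstream tool's exact
rule is not published). Overlapping uORFs are all reported. PAS hits are
every AATAAA/ATTAAA occurrence in the 3' UTR; MBE hits match
(A/G)T{1,3}AGT left-to-right, one per start position. uORFs are only ever
reported for 5' UTRs, PAS/MBE only for 3' UTRs, enforced at the type
level. Rank-order summaries report counts and proportions, ties broken by
element name. Only these three element classes are implemented; IRES and
the long tail of structural UTR patterns are out of scope because they
are defined by secondary structure, not sequence consensus.

## Synthetic studies

The generator emulates the data *shape* of an embryonic FAIRE study on a
scaffold genome. Defaults (all configurable):

* peak width ~ N(550, 60) bp clipped to ±40 % — the 550 bp extent of the
  study design;
* 5 % of peaks promoter-proximal, split 60/40 between peaks straddling
  the TSS (summit ~N(150, 40) bp upstream, i.e. inside the 100–200 bp
  enrichment window) and peaks fully upstream within 100 bp;
* 10 % upstream peaks at 300–950 bp; 7.5 % intragenic, split
  exonic : intronic : boundary = 767 : 4434 : 3991; 1 % upstream of
  non-coding genes (tRNA/rRNA/snRNA/miRNA); the remainder intergenic in
  non-overlapping slots;
* expression ~ base × lognormal(σ = 0.5), 15 % of genes unexpressed, and
  a 1.4× multiplicative effect for genes with a peak ≤ 100 bp upstream;
* SNPs placed uniformly (or partitioned inside/outside peaks at a set
  fraction), reference alleles read from the generated genome;
* motif consensus instances planted at 1/kb of peak sequence
  (Poisson-distributed, non-overlapping), and UTR elements planted at
  rates uORF 1.2, PAS 0.7, MBE 0.5 per gene on backgrounds scrubbed of
  chance matches, so that uORFs are about half of all planted elements.

Genes are placed non-overlapping with intergenic gaps large enough
(≥ ~2 kb reserved on each flank, scaled up with the expected intergenic
peak load) that a peak planted relative to one gene cannot stray into
another gene's upstream or promoter window — planted categories are
recoverable exactly, by construction. The truth JSON records every
planted quantity; where later sequence writes can overwrite a plant
(peaks overlapping UTRs, rare intragenic peak overlaps), truth keeps only
plants whose text survives verbatim in the final genome, verified by
string comparison, never by the detectors under test.

A single seed drives per-component child generators, so bundles are
byte-identical under a fixed config and partial regeneration is stable.

What the generator does **not** emulate: read-level data (no FASTQ/BAM),
realistic base composition (uniform background, with dinucleotide
shuffling available on the analysis side), overlapping gene models,
transcript isoforms, and linkage structure among SNPs. Passing tests
therefore demonstrate correctness of the analysis logic under the planted
statistical structure, not performance on real libraries.

## Problem sizes and numerics

The test suite runs the classifier oracle on 100 random instances (up to
100 genes × 1000 peaks), parameter recovery at 20,000 peaks
(binomial 99 % CIs), expression-fold recovery at 2000 genes per distance
group, and 200-dataset calibrations for both resampling p-values; the
published-scale resampling reproduction uses the full 121,600-peak
population with 1000 replicates, which completes in seconds. Quantile
reporting uses empirical 2.5 %/97.5 % replicate quantiles. All
randomness flows through `numpy.random.Generator` seeded explicitly;
identical seeds give identical outputs everywhere, including file-level
SHA-256 of generated bundles.

## Known limitations

* Gene-level classification only; a peak in an exon of one isoform and an
  intron of another is resolved by the flattened gene model.
* The Clover-style score is a documented simplification; published
  incidence tables from the real genome and the historical JASPAR
  release are not reproducible here and are not targeted.
* The assortment test's empirical p is conservative for very sparse SNP
  counts (see above).
* UTR detection scans whole UTR sequences of peak-linked genes by
  default; an FP-restricted mode (scanning only the peak-overlapped
  portion) is available through the annotation's per-gene linkage but is
  not the default, since element context extends beyond the peak edge.
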