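# Methods

`kskpipe` re-implements, as a tested pipeline over synthetic data with
planted truth, the four computational analyses used to explain stable male
flower production in a hexaploid persimmon cultivar: (1) cultivar-specific
k-mer cataloging of mRNA-Seq reads with contig assembly, (2) RPKM-based
differential expression with a paired all-cultivar intersection rule,
(3) a signed weighted co-expression network with module enrichment, and
(4) bisulfite amplicon methylation profiling. This note records the models,
parameter choices and known limits.

## Study design emulated by the simulator

One target cultivar (stably male-flowering) is contrasted against a pool of
14 predominantly female-producing cultivars; buds are sampled at two branch
positions (`#1` medial, `#2` top) that act as biological replicates, giving
a (1 + 14) x 2 sample design. Reads are 50-bp single-end, error-free by
default, drawn uniformly along transcripts at a mean per-base coverage of
30 (reads per transcript = `round(depth * length / read_length)`). All
generators are pure functions of `(config, seed)`; identical seeds give
byte-identical FASTA/FASTQ/TSV output — the pipeline manifest hashes every
file to enforce this.

Planted target-specific polymorphisms come in four classes: foreign
transcripts (~1 kb, sampled as random trinucleotide strings so their
composition is distinct from the uniform-base reference and all their
k-mers are novel), a 38-bp insertion in a host transcript, deletions, and
single-base substitutions. SNPs intentionally generate few novel k-mers
(on average ~k/4 anchored windows overlap one substituted base) and serve
as the "minor polymorphism" class the contig filter is designed to remove.

## Anchored k-mer cataloging and contig recovery

Catalogs hold counts of every 35-mer whose first base is `A`, scanned along
reads exactly as sequenced. No reverse-complement canonicalisation is done
by default (a `canonical` switch exists): the subtraction logic depends on
stranded-scan semantics, and the simulator emits forward-strand reads only.
Windows containing non-ACGT symbols are dropped, never expanded — ambiguity
codes would fabricate specificity. Target-specific k-mers (KSK) are those
present in the target catalog (count >= `min_target_count`, default 1) and
with strictly zero counts in the pooled background catalog.

Reads containing at least one KSK are recruited and assembled with a
deterministic greedy overlap-layout assembler: repeatedly merge the pair of
sequences with the longest exact suffix-prefix overlap (>= 25 bp), absorb
exact containments, and emit unmergeable reads as singleton contigs. Ties
are broken by longer resulting contig, then lexicographically smaller
resulting sequence, so output is reproducible byte for byte. An optional
`max_mismatch` (default 0) enables a quadratic fallback for noisy fixtures.
This replaces a closed-source commercial assembler; at transcript/amplicon
scale with error-free reads the greedy merge reconstructs each planted
sequence essentially in full (tests require >= 95% length recovery), and
determinism matters more here than assembly sophistication. Distinct KSK
are then remapped onto each contig by exact substring match, and contigs
with fewer than 10 distinct KSK are discarded (the published noise filter);
the report flags contigs with more than 80 KSK.

## Differential expression

RPKM is `count * 1e9 / (length_bp * library_size)` with the library size
being total counted reads. The effect-size filter ("bias") is the fold
ratio larger-mean/smaller-mean with a pseudocount of 0.1 on both terms, so
zero means stay finite; the ratio orientation and pseudocount are this
package's declared convention.

Two selection procedures are implemented. *Comparison I* contrasts the
target (n=2) against the pooled cultivars (n=28) and keeps genes with
Benjamini-Hochberg FDR <= 0.01, max group-mean RPKM > 1 and bias > 2.
*Comparison II* runs one contrast per background cultivar — target versus
that cultivar, pooling matched branch positions — and intersects: a gene is
kept only if significant at the cultivar's raw alpha (0.1 for the two
designated lenient cultivars, 0.05 for the other twelve) with the same
direction in all 14 comparisons, plus the RPKM floor.

The per-gene test engines are deliberately simple stand-ins; the
reproduced contract is the filter and intersection logic, not the numerics
of any shrinkage-based DE package (explicitly out of scope):

- Group contrast: Student t with pooled variance on log2(RPKM+1). A Welch
  test was considered and rejected: with n=2 vs 28 its Satterthwaite
  degrees of freedom are ~1.1, giving a near-Cauchy null in which no effect
  size can reach FDR 0.01. The generator produces equal group variances, so
  the pooled-variance null is exact there; on 20-seed null simulations the
  pooled p-values are uniform (KS statistic <= 0.05, our documented
  tolerance) and the empirical FDR at q=0.01 stays at or below nominal.
- Paired contrast: exact conditional binomial — given the gene's total
  reads across the two samples being compared, the target's share is
  binomial with probability equal to the target's share of the combined
  library. Two-sided p is twice the smaller tail, capped at 1. Position
  blocking is implemented by summing matched-position counts within each
  pairing before conditioning; an exact stratified test has no simple
  closed form and would not change the intersection semantics. This test
  ignores biological overdispersion and is therefore anti-conservative per
  comparison; the all-14 same-direction intersection is what supplies
  specificity, mirroring the original design's logic.

## Co-expression network

Input is log2(RPKM+1) (declared convention). Edge weights are the signed
soft-threshold adjacency `((1 + r)/2)^beta` with Pearson r and beta = 5;
anticorrelation maps near 0. The scale-free criterion bins whole-network
connectivity into 10 equal-width bins and computes the squared Pearson
correlation of log10(mean k) vs log10(frequency) over non-empty bins; a
sweep helper returns the smallest beta with R^2 > 0.6. This binned fit is a
declared simplification of the truncated-model fit used by the standard
WGCNA tooling.

Modules are obtained from average-linkage hierarchical clustering of
1 - TOM, where `TOM_ij = (sum_u w_iu w_uj + w_ij) / (min(k_i,k_j) + 1 - w_ij)`,
cut at a static height with minimum module size 30; smaller clusters stay
unassigned (module 0) and modules are renumbered by decreasing size. The
static cut replaces dynamic dendrogram cutting (out of scope), so published
module *counts* are not reproduction targets — the supported claims concern
enrichment and thresholding. The default cut height 0.8 was chosen from the
merge-height geometry of the simulated regime: within-module merge heights
sit near 0.6 and unrelated-gene dissimilarities near 0.95, while at 30
samples two module latents can correlate ~0.3-0.5 by chance, pulling
between-module dissimilarity below 0.9; 0.8 sits mid-margin. The module
recovery tests assert their own premise (near-orthogonal block latents)
because a draw in which two blocks are genuinely correlated *should* be
merged by any clustering method.

The visualised subnetwork keeps edges with weight strictly > 0.43; hubs
have strictly > 50 connections in that thresholded graph (both boundaries
are exclusive by specification). Module over-representation of a DEG set is
a one-sided Fisher exact test computed as a log-sum-exp over hypergeometric
log-pmf terms, so tables with p below 1e-300 keep a finite log10 p (a
~1e-1200 table is part of the test suite). Zero overlap gives p = 1 by the
one-sided convention.

## Bisulfite amplicon methylation

Cytosine contexts (CG, CHG, CHH; H in {A,C,T}) are classified from the
reference on both strands; cytosines whose context is truncated by the
amplicon end are labelled NA and excluded from level summaries. Reads match
the amplicon ungapped at the offset minimising mismatches after C->T
collapsing (top strand) or G->A collapsing (bottom strand, read
reverse-complemented first); the better strand wins and reads below 90%
collapsed identity are discarded, not clipped — appropriate for amplicon
sequencing of a known short region, and the stated reason indel handling is
omitted. At each strand-matched cytosine, C counts as methylated and T
(A on the bottom strand) as unmethylated; other bases are ignored.
Per-context levels pool counts across sites. The simulator draws each
read's methylation state per cytosine independently from the context
probability (no epiallele structure) and converts unmethylated cytosines
with probability `conversion_efficiency` (default 1).

Two-profile comparison reports a per-site two-sided Fisher exact test on
the methylated/unmethylated table plus an aggregate paired Wilcoxon
signed-rank over per-site methylation fractions. The aggregate test is a
declared design choice (flagged in the output); when every per-site
difference is zero the aggregate p is 1 by convention. The default
simulation probabilities (CG 0.628, CHG 0.594, CHH 0.05 at 500 reads per
strand) exercise parameter recovery at levels typical of a heavily
methylated transposon insertion; recovery within 3 percentage points
follows from the binomial error at this depth.

## Problem sizes and runtime

Default end-to-end conditions: 20 transcripts of 500-1,500 bp, 15 cultivars
(14 pool + 1 target) at 30x (≈190k reads total), a 600-gene count matrix
with 30 up / 30 down planted DE genes at log2FC 3 and three modules of
60/40/40 genes, and a 400-bp amplicon at 2 x 500 reads. These sizes give a
full pipeline run in a few seconds on one CPU while keeping every filter
boundary (KSK >= 10, FDR, 14-way intersection, module minimum size, hub
threshold) exercised with real margins. Background genes vary with log-sd
0.3 (typical bulk biological noise); module genes follow a strong shared
latent program (log-sd 1.0, shared fraction 0.8), which is why module-1
DE genes are intentionally hard for the per-gene group test and are instead
recovered by the count-based paired intersection — the same tension between
co-expression structure and per-gene testing present in real data. NB
dispersion defaults to 0.05.

## What the synthetic data does and does not show

Passing tests demonstrate the pipeline's logic: exact oracle equivalence of
the k-mer chain, perfect recovery of planted foreign transcripts and
insertions under error-free reads, strict filter boundaries, calibrated
null behaviour of the stand-in tests, module recovery under planted
correlation, and byte-level determinism. They do not demonstrate robustness
to sequencing error profiles, strandedness mixtures, splice isoforms, PCR
duplicates, alignment ambiguity in polyploid transcriptomes, or the
numerics of DESeq/edgeR/WGCNA — all declared out of scope. Headline counts
from the motivating study (numbers of contigs, DEGs and modules) depend on
the deposited sequencing data and those external tools and are not targets
of this package.
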