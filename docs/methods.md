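# Methods

This note documents the models, defaults and design choices behind each
stage, what the synthetic generator does and does not emulate, and the
numerical conventions used throughout.

## Coordinates and formats

All intervals are 0-based half-open internally (BED semantics); GTF is
converted at the I/O boundary (1-based inclusive on disk). SAM/BAM is read
and written through pysam, FASTA/FASTQ through Biopython. This single
convention eliminates the usual off-by-one class of bug when intersecting
alignment blocks with exon/CDS intervals.

## Synthetic data generator

The generator exists so that every downstream stage can be exercised with
known ground truth; it is deliberately minimal where realism would not
change what the stages compute.

**Reference.** One chromosome (60 kb by default) of i.i.d. uniform A/C/G/T
— no repeat structure, since none of the stages is repeat-aware. Embedded
gene loci: two 2-isoform coding genes (one pair sharing a skipped exon,
one pair of equal-length isoforms with a shared first exon, to make the EM
identifiable but non-trivial), a 1-isoform coding gene on the minus
strand, a 2-exon lincRNA, single-exon snoRNA/snRNA/miRNA/Mt_tRNA loci
(130/160/85/72 nt), and a coding gene with zero abundance everywhere used
as a negative control for detection. rRNA analogs are generated
independently of the genome (28S/18S/5.8S/5S at 2000/1200/160/120 nt —
scaled down ~2.5× from the real subunits to keep the exhaustive matcher
oracle tractable); a flag can embed one rRNA copy into the genome to
exercise the partition-before-genome ordering.

**Libraries.** Each read: origin class first (rRNA with probability
`rrna_fraction`), then a source weighted by relative abundances (rRNA
subunits weighted 5 : 4 : 0.5 : 0.5 so 28S/18S dominate, as observed in
vesicle preparations), then a fragment uniform over the source. Fragment
lengths are uniform over 30–500 nt (only a range is known for the real
libraries), clamped at the top to the source length; a configuration whose
minimum fragment exceeds any positively-weighted source length is
rejected with the offending sources named. The exosome-like profile uses
rRNA fraction 0.97 with transcript : intergenic weight 1 : 0.5 (≈ 2%
known-gene and ≈ 1% intergenic reads overall); the cell-like profile uses
0.24 with weight 1 : 0.3 (≈ 58% known-gene reads). These are the two read
economies the pipeline is designed to distinguish.

**Qualities, adapters, errors.** Quality strings are a constant mean Phred
(35) with an exponential 3′ decay (e-folding 4 nt over the last 12) —
enough to exercise tail trimming without destroying short reads.
Adapters: with probability 0.2 the full adapter is appended error-free, so
exact-overlap trimming is exercised deterministically. Substitution errors
are available (`error_rate`) but default to 0; the default profiles are
therefore exactly recoverable, which is what the recovery tests assert.
Not emulated: indels, homopolymer (flow-based) error modes, coverage bias,
polyclonal artifacts, strand-specific library chemistry. Consequently,
passing recovery tests demonstrates the correctness of the *analysis
logic*, not robustness to real-instrument noise.

**Truth alignments.** Transcript reads are emitted as spliced SAM records
with `N`-gapped CIGARs and NH=1 at a configurable MAPQ; rRNA reads are
emitted unmapped (the rRNA stage, not the genome aligner, owns them). This
stands in for an external spliced aligner and makes end-to-end runs
self-contained; alignment *errors* are therefore out of scope of the
end-to-end tests.

## Read QC

Adapter trimming removes the longest read suffix exactly matching an
adapter prefix of ≥ 5 nt. Exact matching (no mismatches) keeps the
operation bit-stable and testable by enumeration; error-tolerant trimming
was not needed for the study conditions. Quality trimming removes the
maximal trailing run below Q15; reads shorter than 6 nt are then dropped
(the original analysis retained reads down to 6 bp; its quality threshold
is unstated, so Q15 is this package's explicit default, not an inherited
value). Instrument-level filters (off-scale signal, polyclonal wells)
cannot be reproduced from FASTQ and are carried as an explicit zero
counter so funnel accounting stays complete.

## rRNA partition

Fragments of rRNA are contiguous, so matching is ungapped: the full read
is placed at every offset of every subunit in both orientations and scored
by Hamming distance (defaults: ≤ 2 mismatches, minimum read length
min(20, read length), forward orientation wins ties; further ties break by
fewest mismatches, subunit name, smallest offset). A 12-mer seed index
accelerates the scan with a pigeonhole guarantee (3 disjoint seeds for a
2-mismatch budget); reads too short for the guarantee fall back to the
exhaustive scan, so the matcher is exactly equivalent to the all-offsets
oracle it is tested against. Per-subunit density profiles count, for every
base, the fragments covering it; their sum equals the total matched length
(a conservation law asserted in tests).

## Post-alignment filtering

Filters run in a fixed order — multi-mapped reads (NH tag, or grouping by
read id when NH is absent), aligned length < 20 nt, MAPQ < 10 — so the
funnel counts are well-defined; a record failing several criteria is
counted at the first stage that rejects it. "Aligned length" is the sum of
reference-consuming block lengths, not the read length (the two differ
under soft-clipping; the filter targets the aligned span). CIGAR `N` runs
split records into blocks; `D` consumes reference within a block; `I/S/H/P`
consume none. Compartment labels: rRNA comes from the partition stage;
otherwise a record is a known-gene read iff any block overlaps any
annotated exon by ≥ 1 base (exon-level overlap is the stricter, testable
reading of "intersected with gene models"), else unknown.

## Coverage detection

Coverage is breadth, not depth: covered bases are the size of
(union of blocks) ∩ (union of target intervals), overlapping reads counted
once; the target is CDS for coding transcripts and the exon union for
non-coding ones. Strand is ignored when intersecting (library strandedness
is unknown); a read may contribute to several overlapping transcripts —
detection is a per-transcript property, and ambiguity is the
quantification stage's problem, not the detection stage's.

Thresholds are strict inequalities (literal reading of "over 90%" /
">50%"): cellular detection at fraction > 0.9; exosomal detection of
transcript *t* in sample *S* iff the pooled exosomal fraction > 0.9 AND
sample-*S* fraction > 0.5. The pooled/per-sample rule is one reading of an
ambiguous procedure description and is isolated in a single function
(`detect_exosomal`) so it can be swapped. Pooling dominance (pooled ≥
each per-sample fraction) is enforced as a runtime error because it is
impossible by construction. Genes are detected iff any isoform is; a gene
whose detected isoforms carry conflicting non-coding biotypes is reported
once under the lexicographically smallest with a warning.

## Quantification

The EM treats θ as the read-fraction simplex over all isoforms: E-step
weight θᵢ/ℓᵢ over an equivalence class's compatible isoforms, M-step
θᵢ = massᵢ/n. Reads are collapsed into equivalence classes by compatible
isoform set, which leaves the fixed points unchanged and makes iterations
cheap. Compatibility requires every block inside the isoform's exon union
and every junction between consecutive blocks to coincide with an
adjacent-exon boundary pair within `tolerance` bases (default 0);
incompatible-with-all reads are dropped and counted. Effective length is
the plain exon-union length — no fragment-length correction, the simplest
defensible model given that the original tooling is a black box.
Initialization is uniform, convergence at max |Δθ| < 1e-8 or 1000
iterations; the log-likelihood is asserted non-decreasing every iteration
and total mass is conserved to 1e-9. Isoforms with no compatible reads get
θ = 0. Because the model is global over the isoform set, reads can only
redistribute within their compatibility class, so per-connected-component
and global EM coincide.

RPKM = 10⁹ · mass / (ℓ · total), with total = all post-filter
genome-mapped reads, excluding the rRNA partition (quantification happens
after rRNA removal); whether to include rRNA reads in the denominator is
exposed to the caller by passing a different total. The RPKM > 1 rule is
kept as a separate detector for comparing the two approaches — a short
transcript with 4 reads can exceed RPKM 60 in a shallow library while
covering ~20% of its CDS, which is exactly the failure mode that motivates
breadth-based detection.

## Statistics

**EASE score.** One-sided hypergeometric upper tail with the list-hit cell
reduced by one: p = P(X ≥ k−1), X ~ Hypergeom(N, K, n); k ≤ 1 gives p = 1.
This is deliberately conservative relative to Fisher's exact test
(asserted as a property). Categories with fewer than 5 list hits are
excluded before testing; BH runs across the surviving categories; the
significance call is q < 0.05 and the EASE pass flag is p ≤ 0.1. BH can be
applied per category namespace by passing separate annotation objects.
The annotation is a user-supplied table; no ontology hierarchy or
redundancy trimming is reimplemented.

**Wilcoxon rank-sum.** Midranks for ties. Exact branch (n ≤ 12, no ties):
the rank-sum distribution is built by dynamic programming over rank
subsets, which equals full enumeration (tested against it); two-sided
p = min(1, 2·min(lower tail, upper tail)). Otherwise a normal
approximation with tie correction and a 0.5 continuity correction;
identical samples return p = 1.

**qPCR.** Fold change 2^(−ΔΔCt) with ΔCt = Ct(gene) − Ct(control) and
ΔΔCt taken against a calibrator sample; the calibrator maps to exactly
1.0 by construction.

## Pipeline and problem sizes

The orchestrator validates the configuration up front (aggregating all
missing-input errors before any stage runs), logs stage counts, writes one
TSV per stage plus a JSON manifest, and is byte-reproducible for a fixed
seed (per-sample seeds are derived from the run seed and a CRC of the
sample label). Default runs use 20,000 reads per library — at the toy
reference's scale this reproduces the published read-economy regimes with
binomial sampling error well inside the tested 3-SD bands, while a full
run of three libraries completes in well under a minute on one core. The
EM grid-search oracle runs at step 0.001 on 2–3 isoform fixtures of ≤ 200
reads; the matcher equivalence oracle uses reads ≤ 60 nt against
references ≤ 300 nt, where the exhaustive Hamming scan is exact and cheap.

## Known limitations

* The rRNA matcher is ungapped by design; indel-containing rRNA fragments
  would leak into the genome-alignment branch.
* Coverage detection inherits the annotation: misannotated or truncated
  models shift fractions directly.
* The EM has no fragment-length or positional-bias model, so θ for
  near-identical isoforms of very different lengths carries a small,
  length-dependent bias (bounded in the recovery test at < 0.05 absolute
  for 5,000 reads).
* Enrichment results depend entirely on the supplied category table;
  published category counts from a proprietary 2013-era annotation
  database are not reproducible and are not targeted.
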