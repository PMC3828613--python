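# exorna

Analysis toolkit for RNA-seq of extracellular-vesicle (exosome) RNA, where
libraries are dominated by **fragmented ribosomal RNA** and conventional
abundance-based transcript detection breaks down.

Exosomal RNA preparations typically yield ~97% rRNA fragments that tile the
full length of the 28S/18S/5.8S/5S subunits, leaving only a few percent of
reads for everything else. At such shallow effective depth, RPKM-based
detection (RPKM > 1 in at least one sample) flags transcripts supported by a
handful of reads covering a small slice of the gene. This package implements
the alternative workflow built around **breadth of coverage**:

1. **QC** — adapter suffix trimming, 3′ low-quality tail trimming, minimum
   length filtering (reads down to 6 nt are retained).
2. **rRNA partition** — reads are matched (ungapped, both orientations,
   Hamming distance with a mismatch budget) against the rRNA reference set
   *before* genome alignment; matches are split off and per-subunit fragment
   density profiles are produced.
3. **Post-alignment filters** — multi-mapped reads removed entirely, aligned
   length < 20 nt removed, MAPQ < 10 removed, in that order, with exact
   funnel accounting; spliced alignments are split into blocks at CIGAR `N`
   runs (BED semantics, 0-based half-open).
4. **Compartments** — kept reads are labelled rRNA / known gene (≥ 1 base of
   exon overlap) / unknown.
5. **Coverage detection** — per transcript, the fraction of the target
   (CDS for protein-coding, exon union for non-coding) covered by the union
   of aligned blocks. A cellular transcript is detected iff the fraction
   exceeds 0.9. For exosomal samples the reads of all exosomal libraries are
   pooled: a transcript is detected in sample *S* iff pooled fraction > 0.9
   **and** the sample-*S* fraction > 0.5. Genes are detected if any isoform
   is; summaries report the coding/non-coding split and per-biotype counts.
6. **Quantification** — isoform-level EM: reads compatible with several
   isoforms are apportioned ∝ θᵢ/ℓᵢ (E-step) and θ re-estimated from the
   assigned mass (M-step); RPKM = 10⁹·c/(ℓ·M) with the RPKM > 1 rule kept as
   the comparison detector.
7. **Statistics** — EASE-score Fisher enrichment (hypergeometric upper tail
   with the list-hit cell reduced by one; count threshold 5, EASE 0.1,
   Benjamini–Hochberg q < 0.05), Wilcoxon rank-sum comparison of expression
   distributions, and qPCR fold changes as 2^(−ΔΔCt).

A first-class **synthetic-data generator** builds a toy reference (rRNA
analogs + an annotated chromosome with multi-exon coding and non-coding
loci) and simulates exosome-like (97% rRNA) and cell-like (24% rRNA)
libraries of 30–500 nt fragments with per-read ground truth and truth
alignments in SAM, so the full pipeline runs and is testable without any
external data or aligner.

## Worked example

Run the whole workflow on the default synthetic scenario (one cell-like and
two exosome-like libraries of 20,000 reads each):

```sh
exorna run-all --out run --n-reads 20000 --seed 1
```

or from Python:

```python
from exorna import pipeline
cfg = pipeline.PipelineConfig(
    output_dir="run", seed=1, n_reads=20_000,
    samples=[
        pipeline.SampleConfig("cell_231", "cellular", simulate="cell"),
        pipeline.SampleConfig("exo_231", "exosomal", simulate="exosome"),
        pipeline.SampleConfig("exo_436", "exosomal", simulate="exosome"),
    ])
bundle = pipeline.run_pipeline(cfg)
print(bundle.tables["rrna_partition"][["sample", "rrna_fraction"]])
```

Output from this exact run:

```
     sample  rrna_fraction
0  cell_231        0.23740
1   exo_231        0.96995
2   exo_436        0.96980
```

The partition recovers the simulated regimes (24% rRNA cell-like, 97%
exosome-like). The compartment table from the same run shows the expected
read economy — in the cellular library most reads land in known genes,
while in the exosomal libraries only ~2% do:

```
  sample compartment  percent
cell_231        rRNA     23.7
cell_231  known_gene     58.5
cell_231     unknown     17.8
 exo_231        rRNA     97.0
 exo_231  known_gene      1.9
 exo_231     unknown      1.1
```

`run/` further contains the QC report, per-subunit rRNA density profiles,
the filter funnel, per-transcript coverage fractions and detection calls,
EM/RPKM abundance tables, biotype summaries, set overlaps and a
`manifest.json` listing every stage output. All expressed transcripts are
fully tiled at this depth and are detected; the zero-abundance control
transcript never is.

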