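# chromduet

Tools for asking whether two chromatin factors — for example a transcription
factor and a histone deacetylase it recruits — directly co-repress a common
set of target genes, and for tracing what happens to those targets when the
recruiting factor is removed.

The package implements, end to end and against a fully synthetic test bed,
the evidence chain used in melanoma phenotype-switching studies of this
design:

1. **Consensus co-binding (CUT&RUN).** Peaks are called per antibody track
   against a negative control (anti-FLAG/IgG), SEACR-style: the track is
   decomposed into maximal blocks of positive signal and a block is kept when
   its signal mass (AUC, Σ coverage × width) exceeds a threshold derived from
   the control's block AUCs — the maximum (stringent) or the 90th percentile
   (relaxed), after scaling both tracks to a common library size. With two
   antibodies per factor, loci supported by **at least k = 3 of the n = 4**
   antibodies form the consensus co-bound set; pairwise shared and
   factor-exclusive sets are computed alongside.
2. **Gene assignment and annotation.** Each locus maps to the gene with the
   nearest TSS; peaks are annotated to promoter-TSS / UTR / exon / intron /
   TTS / intergenic categories by their midpoint (HOMER-style windows,
   −1000/+100 bp promoter, −100/+1000 bp TTS).
3. **Differential H3K27ac.** Candidate regions are compared between control
   and knockdown tracks with a fold cutoff and a Poisson tail test
   (fold ≥ 4, p < 10⁻⁴ by default); gained/lost regions are attributed to
   genes through a strand-aware **−15 kb/+10 kb TSS window**.
4. **Differential expression.** External DE tables are filtered with the
   study cutoffs (|log₂ ratio| ≥ 0.27 or ≥ 0.58, p < 0.05, FDR < 0.05,
   Benjamini–Hochberg); a Welch-t stand-in test on log₂ CPM is provided for
   synthetic count tables. ΔΔCt relative expression covers qPCR panels.
5. **Overlays and enrichment.** Set intersections (co-bound ∧ up, gained ∧
   up, lost ∧ down), a signed ranked signature, and a GSEA-preranked-style
   weighted Kolmogorov–Smirnov enrichment statistic (weight exponent 1,
   resampled gene-set null, 1000 permutations, minimum 15 shared genes).
6. **Phenotype metrics.** Lung micrometastasis scoring from GFP⁺ lesion
   counts (0: <5; 1: ≥5; 2: ≥20; 3: ≥50; 4: ≥100), xenograft volume
   V = ⅔·π·((a+b)/4)³ from caliper length/width, and transwell invasion
   quantification from membrane scans (8-bit → invert → rolling-ball-style
   background subtraction, radius 50 px → isodata threshold →
   distance-transform watershed → particles of 50–700 px area and 0.7–1.0
   circularity inside a circular ROI).

A deterministic synthetic-data generator (`chromduet.simulate`) produces a
miniature genome with planted co-bound loci, antibody-specific dropout and
epitope masking, coupled acetylation gains/losses, and a replicate count
table — together with a ground-truth ledger, so the whole chain is testable
without any sequencing download.

## Worked example

One config-driven run generates the synthetic dataset and executes the full
chain:

```sh
cat > run.yaml <<EOF
outdir: demo_run
seed: 7
preset: human_sisall4
consensus_k: 3
simulate:
  seed: 7
EOF
chromduet pipeline run --config run.yaml
```

The report (`demo_run/report.json`) mirrors the count chain of this study
design. With the default simulation (2 chromosomes × 5 Mb, 300 genes, 60
planted co-bound plus 30 + 30 factor-exclusive loci) and seed 7 it prints:

```
counts:   peaks_A1 89, peaks_A2 87, peaks_B1 91, peaks_B2 86,
          shared_A 80, shared_B 84, consensus_loci 60 (in 60 genes),
          a_only 27, b_only 29, gained_ac_genes 26, lost_ac_genes 31,
          up_genes 20, down_genes 27
overlays: direct_up 20, gained_up 20, lost_down 25, direct_gained_up 20
enrichment: invasive  es +1.00, p < 0.001 (n_overlap 20)
            proliferative es −1.00, p < 0.001 (n_overlap 27)
```

Reading: all 60 planted co-bound loci are recovered as 3-of-4 consensus
loci; the 20 genes that gained acetylation *and* rose in expression are
exactly the planted derepressed targets; the planted "invasive" gene set
concentrates at the top of the knockdown expression ranking (enrichment
score +1) and the planted "proliferative" set at the bottom (−1), the
directional signature of a phenotype switch.

Every stage is also exposed as a subcommand on its own files
(`chromduet callpeaks / consensus / annotate / tsswindow / diffpeaks / de /
enrich / invasion / metscore / volume`), so externally produced BED/bedGraph
peak sets or DESeq2/edgeR result tables can be substituted at any point.

## Scope notes

Read alignment, negative-binomial GLM internals (DESeq2/edgeR), de novo
motif discovery and proprietary process-network enrichment are out of scope;
their outputs are accepted as inputs. Coordinates are 0-based half-open
(BED convention) on a single reference genome per run. The ≤120 bp fragment
filter applied to CUT&RUN reads upstream of coverage generation is an input
assumption, not an operation. See `docs/methods.md` for the model, parameter
and calibration details.
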