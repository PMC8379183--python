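# Methods

## Coordinates and data model

All intervals are 0-based, half-open (`[start, end)`), the convention of the
BED and bedGraph formats the pipeline reads and writes. A single reference
genome is assumed per run; mixing assemblies across stages is the caller's
responsibility. On the minus strand the TSS is `tx_end − 1`: under half-open
coordinates the last covered base is the transcript's 5′ end. Coverage
tracks are stored sparsely as sorted, non-overlapping runs of strictly
positive value; explicit zero runs are dropped and abutting equal-value runs
merged on ingestion, so "signal blocks" (maximal positive runs) are
well-defined and their AUCs sum exactly to the track's total signal mass.

## Peak calling

`call_peaks` follows the sparse-enrichment contract used for CUT&RUN data:
the control track is scaled to the treatment's library size, both are
decomposed into signal blocks, and a treatment block is kept when its AUC
exceeds τ = max(control block AUCs) in stringent mode or the 90th percentile
of control block AUCs in relaxed mode. The exact thresholding of the
published sparse-enrichment tool is not reproduced; this quantile contract
approximates its stringent/relaxed behaviour, and externally called peak
BED files can be substituted anywhere downstream. Two consequences are worth
stating plainly:

* the caller is scale-invariant (multiplying both tracks by a constant
  changes nothing), which is the normalisation contract;
* a percentile threshold only separates signal from background when the
  treatment's enrichment is large and its background is sparse — the regime
  CUT&RUN with fragment-size selection actually produces. With dense
  background or weak enrichment, by construction ~10% of background blocks
  exceed the relaxed τ.

An empty control yields τ = 0 (all blocks pass) with a logged warning.

`call_differential_peaks` normalises each track's region mass to counts per
million, then classifies a region as gained when
(B + 1)/(A + 1) ≥ 4 and the Poisson tail P(X ≥ B | λ = A + 1) < 10⁻⁴,
and as lost symmetrically (defaults follow the differential-peak tool the
design is modelled on; the pseudocount of one normalised count avoids empty-
region divisions). Swapping the two tracks maps gained ↔ lost exactly.
Candidate regions default to the union of peaks called in each condition
against an input/background track when one is available. A flat
pseudo-control is not usable under a block-AUC caller — a constant track is
a single chromosome-length block, so its AUC quantile is astronomically
large — and without an input the fallback thresholds each condition's blocks
at the 90th percentile of the two conditions' pooled block AUCs. An explicit
regions BED overrides both.

## Consensus voting

Peaks from n labelled sources are merged transitively (bedtools-merge
semantics, ≥1 bp overlap, chained) into maximal loci; a locus's support is
the set of sources contributing ≥1 peak, and the k-of-n consensus keeps loci
with support ≥ k (default 3 of 4). The locus footprint is the union, not the
intersection, of contributing peaks: chained overlaps can have an empty
common core, and heatmaps are centred on a single merged footprint. Support
counts sources, not peaks. Factor-exclusive sets are pairwise-shared loci of
one factor's two antibodies that overlap no consensus locus. "Overlap"
means ≥1 bp throughout unless overridden — the minimal defensible choice in
the absence of a stated criterion.

## Annotation and gene assignment

A peak's anchor is its integer midpoint (floor on ties). Categories are
resolved in the priority order promoter-TSS > TTS > 5′ UTR > 3′ UTR > exon >
intron > intergenic with the promoter window −1000/+100 bp and the TTS
window −100/+1000 bp, both gene-oriented — the defaults of the annotation
tool this design is modelled on. UTR categories require a CDS span in the
gene model; without one they are unreachable and everything exonic is
"exon". Gene assignment is nearest TSS to the anchor, ties broken by the
smaller TSS coordinate, then lexicographic gene id. The −15/+10 kb TSS
window used to attribute differential acetylation to genes is interpreted
gene-oriented (15 kb upstream, 10 kb downstream), mirrored on the minus
strand and clipped at the chromosome origin; a zero-width request
degenerates to the single TSS base.

## Expression

Cutoff presets apply the printed boundary semantics verbatim: the log₂-ratio
bound is inclusive (≥ 0.27, or ≥ 0.58 for the mouse-contrast preset), the p
and FDR bounds strict (< 0.05). FDR is Benjamini–Hochberg (step-up,
implemented via statsmodels and cross-checked in the tests against the
closed-form definition). The stand-in test for synthetic counts is Welch's
t on log₂(CPM + 1) — deliberately small and dependency-light. It is *not* a
substitute for a negative-binomial GLM on real data: with three replicates
its power is limited by the variance-estimate noise (Welch df ≈ 2–4), and
externally computed DE tables are first-class inputs through the same TSV
schema. ΔΔCt relative expression normalises each gene's Ct to a housekeeping
gene and a reference condition; one PCR cycle less in the treated condition
reads as +1 log₂ unit, and a uniform housekeeping shift cancels exactly.

## Enrichment

The preranked statistic is the weighted Kolmogorov–Smirnov running sum with
weight exponent 1: hits advance the sum proportionally to |score|
(normalised by the summed |score| of hits), misses retreat it by
1/(N − n_hits); ES is the extremum. The null resamples random gene sets of
the same size from the ranked list (seeded), rather than permuting
phenotype labels — a desk-scale approximation of the reference tool's
default scheme; NES divides ES by the mean |null ES| of the same sign and p
is the same-sign null tail fraction. Following the reference tool's run
condition, the statistic is only evaluated when ranked list and gene set
share ≥ 15 genes (n_overlap and an `evaluated` flag are always reported).
Under random gene sets the p-values are uniform (checked by KS test in the
acceptance suite).

## Image quantification

The invasion counter reproduces the standard ImageJ recipe for DAPI-stained
membrane scans: 8-bit conversion, inversion, rolling-ball-style background
subtraction implemented as a grayscale top-hat with a disc of radius 50 px,
automatic isodata ("Default") threshold, distance-transform watershed, and
particle filtering at 50–700 px area and 0.7–1.0 circularity
(4π·area/perimeter², Crofton perimeter, capped at 1.0 against
discretisation overshoot) with the centroid inside a circular ROI. Watershed
markers are the connected h-maxima (h = 1 px) of the distance transform:
touching round nuclei have separate maxima and split, while a single
elongated object keeps one marker and is rejected by the circularity gate
rather than being split into circular halves. For calibration: a digitised
2:1 ellipse measures circularity ≈ 0.86 (ideal 0.84) and passes the 0.7
gate; a 3:1 ellipse measures ≈ 0.69 and is excluded. Background subtraction
makes counting invariant to a constant intensity offset.

## Synthetic data generator

The generator emulates the *structure* of the study data, not its scale:

* **Genome/genes.** 2 chromosomes × 5 Mb, 300 single-transcript genes
  evenly spaced with jitter (~33 kb apart), random strand, 2–4 exons.
* **Planted loci.** 60 co-bound + 30/30 factor-exclusive loci, one gene per
  locus, centred within ±2 kb of the target gene's TSS (inside the
  −15/+10 kb attribution window by construction), width ~N(600, 100) bp,
  placement error if loci fall closer than twice the mean width.
* **Antibody visibility.** Each relevant antibody detects independently
  with sensitivity (0.98, 0.95) per factor — a validated plus a newer
  antibody — with the more sensitive one backstopping so a bound factor is
  visible to ≥1 of its antibodies before masking; epitope masking then
  hides the locus from exactly one visible antibody with probability 0.05.
* **Coverage.** Per-100-bp-bin Poisson background with mean depth 0.05
  (sparse, as fragment-filtered CUT&RUN background is) and a rectangular
  400× enrichment across visible loci; the negative control and the
  H3K27ac input are background-only. These are the conditions under which
  a percentile-of-control-AUC threshold is a faithful separator (see peak
  calling above); they are deliberately favourable in that sense, so
  passing recovery tests demonstrates correctness of the chain, not
  performance on noisy real data.
* **Acetylation coupling.** 60% of co-bound loci gain acetylation after
  knockdown (present in the knockdown track only), 35% lose it (control
  only), the rest and all factor-exclusive loci carry unchanged peaks in
  both conditions. Gains couple to a planted up-regulation with
  probability 0.8, losses to down-regulation with probability 0.9 — gains
  and derepression dominate, as in the repressive-complex biology being
  modelled, while keeping ~20 planted down genes so the "proliferative"
  set clears the 15-gene enrichment run condition.
* **Counts.** Gamma-Poisson with per-gene baseline lognormal(median 300,
  σ = 0.6, floor 100), dispersion 0.005 and planted |log₂FC| = 1.5 over 3
  replicates per condition. This is the low-dispersion/clear-effect regime
  (near-technical replicates of a cell line): the prescribed Welch stand-in
  at n = 3 under a BH gate has ≥90% sensitivity here and nowhere far
  outside it. At dispersion 0 the table is the noise-free limit (rounded
  means).

Everything derives from a single seed; a fixed config reproduces
byte-identical files, and a `manifest.json` echoes the config with SHA-256
hashes of every output. What the generator does **not** model: read-level
artefacts (mappability, GC, duplicates), fragment-size effects, enhancer–
gene looping (every locus regulates its nearest gene by construction),
multi-isoform genes, batch effects, and library-composition effects beyond
what total-count normalisation sees. Recovery results on this test bed are
therefore statements about the pipeline's logic, not about real-data
sensitivity.

## Numerical choices and degenerate inputs

Quantiles use linear interpolation (NumPy default). Poisson tails are
evaluated at the rounded observed count. Ranking ties in signatures break
lexicographically by gene id. Empty controls, gene-free chromosomes,
all-zero genes, regions outside a track's span, blank images and zero-width
TSS windows all have defined, tested behaviour rather than errors where a
sensible value exists. Problem sizes in the test and acceptance suites (the
default 10 Mb genome, 300–2000 gene count tables, 200-run calibration
loops, 512² px image fixtures) are chosen so the whole suite completes in
well under a minute of compute per module while keeping binomial/KS checks
adequately powered.

## Known limitations

* The peak-calling threshold contract is an approximation of the published
  sparse-enrichment tool, not a reimplementation; numbers on real data will
  differ from SEACR's.
* The Poisson differential test treats normalised signal mass as counts;
  with small libraries this conflates coverage depth with read count and is
  anticonservative on mass-inflated units. The defaults are tuned for
  region-level screening followed by the fold cutoff, not for calibrated
  region-level p-values.
* One transcript model per gene; no isoform resolution.
* The stand-in DE test should not be applied to real RNA-seq when a
  negative-binomial tool is available.
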