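# Methods

`icipipe` implements a single-cell tumor/immune analysis of immune
checkpoint inhibitor (ICI) response in advanced non-small-cell lung cancer
(NSCLC): from UMI counts, antibody-derived tags (ADT) and V(D)J contigs to
malignant-cell identification, tumor gene-program signatures, immune
composition statistics and a combinatorial tumor+immune index that
classifies responders (RECIST partial response) against non-responders
(stable or progressive disease). Because the underlying patient data are
controlled-access, a synthetic-cohort generator with full ground truth is a
first-class component: every stage is validated by recovering what the
generator planted.

## Pipeline stages and their models

### QC and normalization

Cells pass QC when the mitochondrial UMI fraction is strictly below 20%,
the number of detected genes strictly above 200, and the doublet flag is
unset (doublet detection is consumed as an input mask, not computed).
Counts are library-size normalized to a scale factor of 10,000 and
log-transformed with the natural log; the scale factor and log base are the
de facto toolchain convention, not independently meaningful. Highly
variable genes are ranked by vst-style standardized variance: a lowess
trend (span 0.3) of log10 variance on log10 mean of the raw counts predicts
each gene's expected s.d.; counts standardized by it are clipped at
sqrt(n_cells) and genes ranked by the variance of the clipped values, ties
broken by gene index. Scaling regresses each gene on numeric covariates
(cell-cycle S and G2M scores — per-cell means of log-normalized expression
of standard phase marker lists) by OLS, z-scores the residuals and clips at
±10. Genes fit exactly by the covariates are set to zero rather than
amplifying numerical noise.

### CD4/CD8/NK gating

Among T/NK-annotated cells, CD3+ means any raw count in CD3D/CD3E/CD3G.
ADT values are transformed per cell by centered log-ratio (CLR over the
marker panel; configurable to raw) and gated at the 55th percentile
(linear-interpolation definition, strict `>`), computed over CD3+ cells.
CD4-only positives are CD4 T, CD8-only CD8 T, dual positives ambiguous,
dual negatives unassigned. CD3− cells are NK when their mean expression of
XCL1/NCAM1/KLRD1/KLRF1 clears the 55th percentile of that score among CD3−
cells (mirroring the ADT convention; the percentile population is
configurable). Ungated cells are labeled by a classifier trained on the
gated cells: 30 reference principal components and a regularized
multinomial logistic model, with labels accepted at posterior ≥ 0.55 and
left ambiguous otherwise. This plays the role of a probabilistic
supervised classifier with a reject option; gate-derived labels are never
overwritten.

Note on invariances: the percentile gate on *raw* ADT is invariant to any
strictly monotone transform of the values. The CLR default trades that
exact invariance for robustness to per-cell ADT depth; with a single-digit
marker panel the CLR denominator is informative only when the panel has
more than two markers (with exactly two, CLR degenerates to a mirrored
log-ratio and the two gates become perfectly anti-correlated).

### CNV inference and malignant calling

Genes are ordered along the genome (chromosome order, then start; genes
without positions dropped; chrM excluded — mitochondrial genes track
library composition, not copy number). Genes with mean raw count below 0.1
are removed. The signal path: per-gene relative expression against the
mean of the immune reference (T/NK, B/plasma, myeloid, mast), clipped at
±3; a centered 101-gene moving average per chromosome with truncated edge
windows; per-cell median centering; a second subtraction of the reference
mean profile; then a noise filter that zeroes entries within 3 s.d. of the
reference-cell signal distribution. The s.d. multiplier is the one free
parameter of the denoising step: it is set so that technical window noise
(depth heterogeneity, sampling noise) sits below the fixed decision
threshold while arm-scale events (several tenths in log space) pass
untouched; values in the 1.5–3 range all preserve planted events by a wide
margin, and 3 gives the cleanest normal-cell profiles.

Cells are summarized by the s.d. of their signal across all windows
(concatenated across chromosomes) and the Pearson correlation with the
mean profile of the top 5% of candidate cells ranked by that s.d.
Candidates (epithelial cells; immune and stromal cells are never called)
are malignant when s.d. > 0.03 or correlation > 0.3. A second caller fits
a two-component Gaussian mixture to per-cell signal variance and labels
the higher-variance component aneuploid; a one-component model preferred
by BIC, or components with indistinguishable means, yields all-diploid —
this guard prevents the mixture from fabricating an aneuploid class on
tumor-free data. The final malignant set is the union of the two callers.
If the epithelial share of the analyzed cells exceeds 20%, normal-profile
cells can be spiked in to dilute it (`spike_reference`).

### Tumor signatures

Differential expression between response groups uses the two-tailed
Wilcoxon rank-sum test on malignant cells, with logFC defined as the
difference of group means of log-normalized expression. Genes reach
testing only with |logFC| > 0.25 and detection fraction ≥ 0.25 in at least
one group; passing further requires p < 0.01 and Bonferroni-adjusted
p < 0.01, with the Bonferroni denominator equal to the number of genes
actually tested (this keeps adj_p ≥ p). Exact enumeration replaces the
normal approximation when both groups have ≤ 8 cells and no ties. The
three comparisons (responder vs non-responder, PR vs PD, PR vs SD) yield
INT (intersection) and UNION sets of up- and down-regulated genes, with
"up" meaning higher in the responder-side group.

NMF runs on the raw UMI counts of malignant cells at rank 30 with
Frobenius multiplicative updates, seeded uniform initialization, and a
relative-error stopping tolerance; the error sequence is non-increasing by
construction and factors are ordered by total loading. Each factor's
loading share per RECIST group is its mean per-cell H loading normalized
across groups; a factor is assigned to its argmax group when the share
exceeds (1/G)(1 + 0.25) — the 0.25 margin is a configurable default for
"clearly enriched", chosen once. A group's program signature is the union
of its factors' top-50 genes by W. Program uniqueness per group is a
Fisher exact test on the 2×2 table of cells assigned to the program
(argmax mean z-scored signature expression) versus group membership, with
Haldane–Anscombe 0.5 correction on the odds ratio when a cell count is
zero, and the log-OR z-scored within each program row. Gene modules take
the top-100 coefficient genes per module (in the pipeline, the W columns
of group-assigned factors) and union them per group. PC signatures come
from a full SVD of the centered, scaled 2,000-HVG malignant matrix: per PC
(1–10), the 30 most positive and 30 most negative loadings, with the sign
fixed so each PC's largest-magnitude loading is positive (making the
output invariant to cell permutation).

Signatures score per sample as the malignant-cell mean of the
signature-gene mean log-normalized expression, divided by the maximum
across samples.

### Repertoire

TCR clonotypes require a TRA+TRB pair, BCR an IGH plus IGK or IGL; the
clonotype key concatenates both chains' locus, V(D)JC genes and CDR3
nucleotide sequence (the "gene+nt" rule). When a cell has multiple contigs
on a chain side, the highest-UMI contig wins, ties broken by lexicographic
CDR3. Clone sizes classify by half-open upper bounds Single = 1, Small ≤ 5,
Medium ≤ 10, Large ≤ 20, Hyperexpanded = ∞; relative clone size divides by
the compartment's paired cells within the sample. Regulatory and cytotoxic
functional scores are per-cell means of the respective log-normalized gene
panels.

### Response classification

Ro/e is observed over expected cell-type-by-sample counts, the expectation
from the chi-square independence model (row total × column total / grand
total). Composition differences between response groups use the two-sided
Welch t-test on per-sample proportions (pooled-variance variant
selectable; denominators available as all-immune or within CD4+CD8). The
univariate screen fits OLS of the 0/1 response on one predictor at a time
(Ro/e features, max-normalized tumor signature scores, dummy-coded
clinical factors) with the predictor's F-test p. Combinatorial indices sum
orientation-aligned max-normalized features — a feature whose univariate
coefficient is negative (non-responder-associated) enters as its value,
a responder-associated one as 1 − value, so higher is more
non-responder-like. All single features plus all pairs among the top-6
univariate features are evaluated by in-sample ROC AUC (Mann–Whitney with
ties counted 1/2, oriented ≥ 0.5) with a two-tailed Wilcoxon rank-sum p,
Benjamini–Hochberg adjusted across all evaluated combinations. In-sample
evaluation mirrors the discovery setting and is optimistic by
construction; no resampling is performed.

## The synthetic cohort generator

The generator emulates a CITE-seq cohort of 14 ICI-treated NSCLC tumor
samples (5 PR / 3 SD / 6 PD), 600 cells and 2,000 genes by default, with:

- **Counts**: gamma-Poisson (negative binomial) UMIs with dispersion 0.05
  around lineage-specific expected profiles scaled by per-cell library
  sizes (lognormal, median 20,000, log-s.d. 0.15). The depth and
  dispersion defaults put reference-cell CNV window noise below the fixed
  decision threshold of the malignant-cell rule — the regime such fixed
  thresholds are designed for; deeper heterogeneity (e.g. log-s.d. 0.25) makes low-depth cells
  bleed through any global noise filter via the log1p depth bias.
- **Lineages**: 14 subtypes (5 CD4, 4 CD8 states, NK, B, myeloid, mast,
  epithelial). Each lineage family diverges from the shared baseline at
  *every* gene by a moderate lognormal factor (σ = 0.25, plus σ = 0.08 per
  subtype) — the dense-divergence regime of real transcriptomes — plus
  sparse canonical markers (≈ 60 genes at 8× in their lineage, leak 0.05
  elsewhere, placed at modest absolute expression and scattered across the
  genome as real markers are). Dense-plus-sparse matters: concentrated
  high-amplitude marker blocks would create window-level artifacts that no
  reference-based CNV method can remove.
- **Composition**: per-sample cell-type proportions from a Dirichlet
  (concentration 150) whose log-mean shifts by response group: +0.7
  log-odds for Treg/TRM/TH17 in non-responders and +0.7 for CD8 TEM in
  responders.
- **Malignancy**: 85% of epithelial cells in each sample carry the planted
  CNV events (default: a 300-gene ×1.5 arm gain on chr1 and a 200-gene
  ×0.6 loss on chr2) and the sample's RECIST tumor programs (default: a
  shared non-responder program of 80 genes ×1.6 in SD+PD, plus smaller
  PR/SD/PD-specific programs). Without CNV events no cell is malignant —
  malignancy in this model *is* aneuploidy.
- **ADT**: a 7-marker panel (CD3/CD4/CD8/CD56/CD19/CD14/CD45), negative
  binomial with positives at mean 300 and background 10; monocytes are
  CD4-dim. A multi-marker panel is required for the CLR gate to be
  non-degenerate (see above).
- **Repertoire**: one TRA+TRB (or IGH+light) pair per T (B) cell; clone
  sizes from a truncated power law per sample and subtype with a heavier
  tail for exhausted CD8 T cells (γ = 1.6 vs 3.0 default); clonotypes
  share V(D)JC genes and random 30–45 nt CDR3 sequences.
- **Nuisance structure**: per-sample patient effects (per-gene lognormal,
  σ = 0.1), a shared cell-cycle program (S/G2M genes ×4 in 15% of cells),
  3% doublets (sums of two same-sample cells, flagged), 2% high-mito and
  2% low-depth cells planted as QC failures, and a pinned 5% baseline
  mitochondrial fraction.

What the generator does **not** model: gene–gene correlation beyond the
lineage/cycle/CNV block structure, batch effects, ambient RNA, spliced vs
unspliced, spatial context, realistic V(D)J recombination biology, and
clinical covariates that genuinely correlate with response. Passing
recovery tests therefore demonstrates that the implementation recovers the
statistical structure it assumes, not that the thresholds would perform
identically on any real dataset.

## Problem sizes and numerical choices

Tests run the default cohort once (≈ 8,400 cells × 2,000 genes), twenty
seeds of the full pipeline for the headline surrogate, ten constructed
replicates for DEG recovery, and 200 reduced cohorts (250 genes × 120
cells/sample, all effects zero) for null calibration of the composition
tests — rejection at α = 0.05 must fall in 0.05 ± 0.02. Reduced scales are
the package's own choice of desk-scale problem sizes; every stated
parameter default is kept at full value throughout.

Degenerate inputs are handled explicitly: zero-total cells are an error at
normalization (QC removes them first); constant genes score zero
standardized variance; collinear covariates are dropped with a warning;
zero-expectation Ro/e cells are NaN; a constant predictor yields an
undefined univariate p; all-identical ADT gates nothing (strict
inequality); degenerate or unimodal mixture fits call everything diploid;
and samples without malignant cells get missing signature scores and are
excluded from affected indices.

## Known limitations

- In-sample AUC on 14 samples is optimistic; the screen reports it as the
  discovery-setting quantity, not an estimate of generalization.
- The aneuploid caller is a deliberately simple variance-mixture stand-in
  for CopyKAT-style callers; its conventional tuning parameters are recorded
  in the configuration for provenance but not interpreted.
- The HMM path of expression-CNV callers is not implemented; malignant
  calling operates on the denoised signal only, which is what the
  s.d./correlation rule consumes.
- scINSIGHT-style joint factorization is not re-implemented; the module
  refinement step accepts any per-module coefficient vectors and the
  pipeline feeds it the group-assigned NMF factors.
- Clone frequency is computed per sample (configurable); cross-sample
  clonotype sharing is out of scope.
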