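# icipipe

Single-cell tumor/immune analysis of immune checkpoint inhibitor (ICI)
response in advanced non-small-cell lung cancer (NSCLC).

Patients receiving anti-PD-(L)1 therapy split into responders (RECIST
partial response, PR) and non-responders (stable disease, SD, or
progressive disease, PD), and the question this package addresses is
whether the composition of the tumor microenvironment plus the expression
programs of the malignant cells can classify that response from a
single-cell biopsy. `icipipe` is a tested, reusable implementation of the
full analysis path for CITE-seq cohorts — UMI counts, antibody-derived
tags (ADT) and paired V(D)J contigs in; a ranked table of tumor+immune
classifier indices out — together with a synthetic-cohort generator that
plants every effect with ground truth, so each stage is validated by
recovery rather than by eye.

The pipeline stages:

1. **QC / normalization** — keep cells with mitochondrial fraction < 20%,
   detected genes > 200, no doublet flag; log-normalize
   (ln(1 + count/total·10⁴)); vst-style highly-variable-gene ranking;
   z-scaling with cell-cycle covariate regression.
2. **T/NK gating** — CD3D/CD3E/CD3G > 0 defines CD3+; CD4/CD8 ADT gated at
   the 55th percentile (CLR-transformed, over CD3+ cells); NK by
   XCL1/NCAM1/KLRD1/KLRF1 among CD3− cells; a PCA + multinomial-logistic
   classifier with reject option propagates labels to ungated cells.
3. **CNV / malignant calling** — genome-ordered, reference-centered,
   101-gene window-smoothed expression signal with noise filtering; a cell
   is malignant when its signal s.d. > 0.03 **or** its correlation with
   the top-5% cells' mean profile > 0.3, in union with a Gaussian-mixture
   aneuploidy caller.
4. **Tumor signatures** — Wilcoxon DEGs (|logFC| > 0.25, p < 0.01,
   Bonferroni p < 0.01, pct > 0.25) combined into INT/UNION sets over the
   three response comparisons; rank-30 NMF programs assigned to RECIST
   groups by relative loading share with Fisher odds-ratio enrichment;
   top-100 gene modules; PC1–10 pos/neg signatures.
5. **Repertoire** — paired-chain clonotypes ("gene+nt" rule), clone-size
   classes Single/Small/Medium/Large/Hyperexpanded (1/5/10/20/∞),
   regulatory and cytotoxic T cell scores.
6. **Classification** — Ro/e (observed/expected composition enrichment
   under the chi-square independence model), Welch t-tests on
   proportions, a univariate linear screen of every feature against the
   0/1 response, and ROC AUC for all single features and all pairs of the
   top-6, with Benjamini–Hochberg correction.

The statistic at the core of the classification step, for a cell type
*t* in sample *s*:

    Ro/e(t, s) = O(t, s) / E(t, s),   E(t, s) = (row_t · col_s) / N

and a combinatorial index for features *f₁, f₂* (each max-normalized
across samples, oriented so higher = more non-responder-like) is their
sum, scored by the Mann–Whitney AUC over responder/non-responder labels.

## Worked example

Run the whole pipeline on a default synthetic cohort (14 samples: 5 PR /
3 SD / 6 PD, 600 cells/sample, 2,000 genes) from the shell:

```bash
icipipe --seed 1 --outdir run1 run-all
```

or from Python:

```python
from icipipe import PipelineConfig, run_pipeline

ctx = run_pipeline(PipelineConfig(seed=1), write=False)
print(ctx["roc_screen"].head(5)[["name", "n_features", "auc", "p", "q"]])
```

which prints:

```
         name  n_features  auc         p         q
0      INT.up           1  1.0  0.000999  0.002229
1    INT.down           1  1.0  0.000999  0.002229
2    UNION.up           1  1.0  0.000999  0.002229
3  UNION.down           1  1.0  0.000999  0.002229
4      NMF.PD           1  1.0  0.000999  0.002229
```

Reading this: each row is a candidate classifier of responder vs
non-responder across the 14 samples — `INT.up` is the intersection of
genes upregulated in responders' malignant cells across all three response
comparisons, scored per sample and max-normalized. An AUC of 1.0 means the
planted effects (a non-responder tumor program of 80 genes at 1.6-fold,
plus +0.7 log-odds composition shifts for Treg/TRM/TH17 in non-responders
and CD8 TEM in responders) separate the two groups perfectly in-sample;
`p` is the two-tailed Wilcoxon rank-sum p-value for the score difference
and `q` its Benjamini–Hochberg adjustment across all evaluated
combinations. The run directory additionally contains the QC report, T/NK
labels, the CNV summary with per-cell malignant calls, all DEG tables and
signatures, clonotype tables, the Ro/e matrix and `classifier_report.md`.

On this cohort the CNV stage calls all 1,081 planted malignant cells
malignant and 5 of 187 normal epithelial cells (sensitivity 1.00,
specificity 0.97); numbers vary slightly by seed.

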