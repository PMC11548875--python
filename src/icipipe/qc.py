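"""Cell QC, normalization, variable-gene selection and scaling.

The conventions are the standard single-cell toolchain ones: library-size
log-normalization to a fixed scale factor (natural log), vst-style
standardized-variance HVG ranking, and per-gene z-scoring of residuals
after regressing out numeric covariates (cell-cycle scores).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort import CellCohort
from .config import NormScaleParams, QcThresholds

log = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Gene x cell log-normalized expression: ln(1 + count/total * sf)."""

    values: np.ndarray
    gene_ids: pd.Index
    cell_barcodes: pd.Index
    scale_factor: float = 1e4

    def gene(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.get_loc(gene_id)]


@dataclass
class ScaledMatrix:
    """Gene x cell z-scored residuals, clipped at +/- clip_bound."""

    values: np.ndarray
    gene_ids: pd.Index
    cell_barcodes: pd.Index
    clip_bound: float = 10.0


def qc_metrics(cohort: CellCohort, thresholds: QcThresholds) -> pd.DataFrame:
    counts = np.asarray(cohort.counts)
    totals = counts.sum(axis=0)
    detected = (counts > 0).sum(axis=0)
    mito_mask = cohort.gene_ids.str.startswith(thresholds.mito_gene_prefix)
    if not mito_mask.any():
        warnings.warn(
            f"no genes with prefix {thresholds.mito_gene_prefix!r}; "
            "mito criterion passes vacuously"
        )
        mito_frac = np.zeros(cohort.n_cells)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, counts[mito_mask].sum(axis=0) / np.maximum(totals, 1), 0.0)
    doublet = (
        cohort.cell_meta["doublet"].to_numpy(dtype=bool)
        if "doublet" in cohort.cell_meta
        else np.zeros(cohort.n_cells, dtype=bool)
    )
    return pd.DataFrame(
        {
            "total_counts": totals,
            "n_genes_detected": detected,
            "mito_fraction": mito_frac,
            "doublet": doublet,
        },
        index=cohort.cell_barcodes,
    )


def qc_filter(cohort: CellCohort, thresholds: QcThresholds | None = None) -> np.ndarray:
    """Boolean keep-mask: mito fraction < max, detected genes > min, not doublet.

    Both comparisons are strict, so a cell at exactly 200 detected genes or
    exactly 20% mitochondrial UMIs is removed.
    """
    thresholds = thresholds or QcThresholds()
    m = qc_metrics(cohort, thresholds)
    keep = (
        (m["mito_fraction"] < thresholds.mito_fraction_max)
        & (m["n_genes_detected"] > thresholds.min_genes_detected)
        & ~m["doublet"]
    )
    log.info(
        "QC: kept %d/%d cells (mito<%g, genes>%d, doublets removed)",
        int(keep.sum()), len(keep), thresholds.mito_fraction_max, thresholds.min_genes_detected,
    )
    return keep.to_numpy()


def log_normalize(
    counts: np.ndarray,
    gene_ids: pd.Index | None = None,
    cell_barcodes: pd.Index | None = None,
    scale_factor: float = 1e4,
) -> NormalizedMatrix:
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        bad = int(np.flatnonzero(totals <= 0)[0])
        raise ValueError(f"cell {bad} has zero total counts; QC should have removed it")
    values = np.log1p(counts / totals * scale_factor)
    n_genes, n_cells = counts.shape
    return NormalizedMatrix(
        values=values,
        gene_ids=pd.Index(gene_ids) if gene_ids is not None else pd.RangeIndex(n_genes),
        cell_barcodes=pd.Index(cell_barcodes) if cell_barcodes is not None else pd.RangeIndex(n_cells),
        scale_factor=scale_factor,
    )


def normalize_cohort(cohort: CellCohort, params: NormScaleParams | None = None) -> NormalizedMatrix:
    params = params or NormScaleParams()
    return log_normalize(
        cohort.counts, cohort.gene_ids, cohort.cell_barcodes, params.scale_factor
    )


def select_hvg(
    counts: np.ndarray,
    gene_ids: pd.Index | None = None,
    n: int = 2000,
    span: float = 0.3,
) -> pd.Index:
    """Rank genes by vst-style standardized variance; return the top ``n``.

    A lowess trend of log10(variance) on log10(mean) of the raw counts
    predicts each gene's expected s.d.; counts are standardized by it,
    clipped at sqrt(n_cells), and genes are ranked by the variance of the
    clipped values. Ties break by ascending gene index, so output is
    deterministic.
    """
    counts = np.asarray(counts, dtype=float)
    n_genes, n_cells = counts.shape
    if n > n_genes:
        raise ValueError(f"requested {n} HVGs but only {n_genes} genes")
    gene_ids = pd.Index(gene_ids) if gene_ids is not None else pd.RangeIndex(n_genes)
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    std_var = np.zeros(n_genes)
    ok = (mean > 0) & (var > 0)
    if ok.sum() >= 2:
        x, y = np.log10(mean[ok]), np.log10(var[ok])
        fitted = lowess(y, x, frac=span, xvals=x)
        sd_pred = np.sqrt(10.0 ** fitted)
        clip = np.sqrt(n_cells)
        z = (counts[ok] - mean[ok, None]) / sd_pred[:, None]
        np.clip(z, -clip, clip, out=z)
        std_var[ok] = ((z - z.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) / (n_cells - 1)
    order = np.lexsort((np.arange(n_genes), -std_var))
    return gene_ids[order[:n]]


def scale_and_regress(
    norm: NormalizedMatrix,
    covariates: pd.DataFrame | np.ndarray | None = None,
    clip_bound: float = 10.0,
) -> ScaledMatrix:
    """Per-gene OLS on covariates, then z-score the residuals and clip.

    With no covariates this reduces to a plain per-gene z-score. Collinear
    covariate columns are dropped with a warning (pivoted by order).
    """
    Y = norm.values
    n_cells = Y.shape[1]
    if covariates is None:
        X = np.ones((n_cells, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n_cells), C])
        X = _drop_collinear(X)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    sd = resid.std(axis=1, ddof=0)
    # genes fit exactly by the covariates carry only numeric dust: zero them
    # instead of amplifying it
    degenerate = sd <= 1e-10 * max(1.0, float(np.abs(Y).max()))
    sd[degenerate] = 1.0
    values = resid / sd[:, None]
    values[degenerate] = 0.0
    np.clip(values, -clip_bound, clip_bound, out=values)
    return ScaledMatrix(values, norm.gene_ids, norm.cell_barcodes, clip_bound)


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear covariate column {j - 1}")
    return X[:, keep]


def score_gene_set(norm: NormalizedMatrix, gene_set) -> np.ndarray:
    """Per-cell mean of log-normalized expression over the set's genes.

    Genes absent from the matrix are dropped with a warning; an empty
    intersection is an error.
    """
    present = [g for g in gene_set if g in norm.gene_ids]
    missing = [g for g in gene_set if g not in norm.gene_ids]
    if not present:
        raise ValueError("gene set has no overlap with the expression matrix")
    if missing:
        warnings.warn(f"{len(missing)} gene(s) absent from matrix: {missing[:5]}...")
    idx = norm.gene_ids.get_indexer(present)
    return norm.values[idx].mean(axis=0)
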