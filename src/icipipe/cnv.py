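"""Expression-based CNV inference and malignant-cell calling.

The signal path follows the window-smoothing approach of expression-based
CNV callers: genes ordered along the genome, per-gene relative expression
against an immune reference, a centered moving average per chromosome,
per-cell median centering, a second reference subtraction, and a noise
filter that zeroes entries within a multiple of the reference signal s.d.
Cells are then summarized by the s.d. of their signal across windows and
the correlation with the mean profile of the highest-s.d. cells; candidates
exceeding either decision threshold (s.d. > 0.03 or correlation > 0.3) are
called malignant. A two-component Gaussian mixture on signal variance acts
as the second, aneuploidy-style caller; the consensus is the union.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .cohort import GenePositionTable
from .config import CnvParams
from .qc import NormalizedMatrix

log = logging.getLogger(__name__)

#: coarse lineages used as the normal reference
REFERENCE_LINEAGES = ("T/NK", "B/plasma", "Myeloid", "Mast")


@dataclass
class CnvProfileMatrix:
    signal: np.ndarray  # windows (gene positions kept) x cells
    window_genes: pd.Index
    window_chromosomes: np.ndarray
    cell_barcodes: pd.Index
    reference_mask: np.ndarray  # per cell
    candidate_mask: np.ndarray  # per cell, cancer-candidate universe
    summary: pd.DataFrame | None = None
    calls: pd.DataFrame | None = None
    params: CnvParams = field(default_factory=CnvParams)


def build_genomic_order(
    positions: GenePositionTable,
    gene_ids: pd.Index,
    exclude_chromosomes: tuple[str, ...] = ("chrM",),
) -> pd.DataFrame:
    """Sort the expressed genes by (chromosome order, start position).

    Genes without positions are dropped (count logged), as are excluded
    chromosomes (mitochondrial genes track library composition rather than
    copy number); an empty overlap is an error.
    """
    tab = positions.table[
        positions.table["gene_id"].isin(gene_ids)
        & ~positions.table["chromosome"].isin(exclude_chromosomes)
    ]
    n_dropped = len(gene_ids) - len(tab)
    if len(tab) == 0:
        raise ValueError("no expressed gene has a genomic position")
    if len(tab) < 0.5 * len(gene_ids):
        warnings.warn(
            f"positions available for only {len(tab)}/{len(gene_ids)} genes"
        )
    if n_dropped:
        log.info("genomic ordering: %d gene(s) without positions dropped", n_dropped)
    chrom_rank = {c: i for i, c in enumerate(positions.chromosome_order)}
    tab = tab.assign(_rank=tab["chromosome"].map(chrom_rank))
    return (
        tab.sort_values(["_rank", "start", "gene_id"])
        .drop(columns="_rank")
        .reset_index(drop=True)
    )


def _truncated_moving_average(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 with edge windows truncated."""
    n = block.shape[0]
    half = window // 2
    csum = np.vstack([np.zeros((1, block.shape[1])), np.cumsum(block, axis=0)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)[:, None]


def infer_cnv_signal(
    norm: NormalizedMatrix,
    reference_mask: np.ndarray,
    gene_order: pd.DataFrame,
    params: CnvParams | None = None,
    candidate_mask: np.ndarray | None = None,
    raw_counts: np.ndarray | None = None,
) -> CnvProfileMatrix:
    """Window-smoothed relative expression signal for every cell.

    Genes with mean raw count below ``expression_cutoff`` are removed (the
    log-normalized mean stands in when raw counts are not supplied).
    Chromosomes with fewer than 3 kept genes are skipped with a warning.
    """
    params = params or CnvParams()
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference cell set is empty")
    if candidate_mask is None:
        candidate_mask = ~reference_mask
    candidate_mask = np.asarray(candidate_mask, dtype=bool)

    basis = raw_counts if raw_counts is not None else norm.values
    gene_mean = np.asarray(basis).mean(axis=1)
    expressed = pd.Index(norm.gene_ids[gene_mean >= params.expression_cutoff])
    order = gene_order[gene_order["gene_id"].isin(expressed)]

    idx = norm.gene_ids.get_indexer(order["gene_id"])
    values = norm.values[idx]
    chroms = order["chromosome"].to_numpy()

    # pass 1: per-gene centering on the reference, clipped
    rel = values - values[:, reference_mask].mean(axis=1, keepdims=True)
    np.clip(rel, -params.clip_bound, params.clip_bound, out=rel)

    keep_rows, smooth_blocks, kept_chroms = [], [], []
    start = 0
    for chrom in pd.unique(chroms):
        block_len = int((chroms == chrom).sum())
        sl = slice(start, start + block_len)
        start += block_len
        if block_len < 3:
            warnings.warn(f"chromosome {chrom} has <3 genes after filtering; skipped")
            continue
        smooth_blocks.append(_truncated_moving_average(rel[sl], params.window_genes))
        keep_rows.append(np.arange(sl.start, sl.stop))
        kept_chroms.append(np.repeat(chrom, block_len))
    signal = np.vstack(smooth_blocks)
    kept = np.concatenate(keep_rows)

    # per-cell median centering, then second reference-profile subtraction
    signal -= np.median(signal, axis=0, keepdims=True)
    signal -= signal[:, reference_mask].mean(axis=1, keepdims=True)
    if params.denoise:
        noise_sd = float(signal[:, reference_mask].std())
        thr = params.noise_sd_multiplier * noise_sd
        signal[np.abs(signal) <= thr] = 0.0
    return CnvProfileMatrix(
        signal=signal,
        window_genes=pd.Index(order["gene_id"].to_numpy()[kept]),
        window_chromosomes=np.concatenate(kept_chroms),
        cell_barcodes=pd.Index(norm.cell_barcodes),
        reference_mask=reference_mask,
        candidate_mask=candidate_mask,
        params=params,
    )


def summarize_cnv_cells(
    profile: CnvProfileMatrix, params: CnvParams | None = None
) -> pd.DataFrame:
    """Per-cell (sd, cor): signal s.d. across windows, and correlation with
    the mean profile of the top ``top_cell_fraction`` candidates by s.d."""
    params = params or profile.params
    n_candidates = int(profile.candidate_mask.sum())
    if n_candidates < 20:
        raise ValueError(
            f"only {n_candidates} candidate cells; top-fraction summary undefined"
        )
    sd = profile.signal.std(axis=0, ddof=0)
    cand_idx = np.flatnonzero(profile.candidate_mask)
    n_top = max(1, int(np.ceil(params.top_cell_fraction * n_candidates)))
    top = cand_idx[np.argsort(-sd[cand_idx], kind="stable")[:n_top]]
    top_profile = profile.signal[:, top].mean(axis=1)

    centered = profile.signal - profile.signal.mean(axis=0, keepdims=True)
    tp = top_profile - top_profile.mean()
    denom = np.sqrt((centered**2).sum(axis=0) * (tp**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.where(denom > 0, centered.T @ tp / np.where(denom > 0, denom, 1.0), 0.0)
    summary = pd.DataFrame(
        {"sd": sd, "cor": cor, "is_top": np.isin(np.arange(len(sd)), top)},
        index=profile.cell_barcodes,
    )
    profile.summary = summary
    return summary


def call_malignant_threshold(
    summary: pd.DataFrame,
    candidate_mask: np.ndarray,
    params: CnvParams | None = None,
) -> np.ndarray:
    """Malignant iff sd > sd_threshold OR cor > cor_threshold, candidates only."""
    params = params or CnvParams()
    candidate_mask = np.asarray(candidate_mask, dtype=bool)
    call = (summary["sd"].to_numpy() > params.sd_threshold) | (
        summary["cor"].to_numpy() > params.cor_threshold
    )
    return call & candidate_mask


def aneuploid_cluster_call(
    profile: CnvProfileMatrix, seed: int = 0
) -> np.ndarray:
    """Two-component Gaussian mixture on per-cell signal variance.

    The higher-mean-variance component is labeled aneuploid. A degenerate
    fit — component means within 1e-3, or a one-component model preferred
    by BIC (no aneuploid subpopulation) — yields all-diploid with a
    warning. Only candidate cells are ever called.
    """
    var = profile.signal.var(axis=0, ddof=0)
    cand = profile.candidate_mask
    x = var[cand].reshape(-1, 1)
    out = np.zeros(len(var), dtype=bool)
    if len(np.unique(x)) < 2:
        warnings.warn("degenerate signal variance; all cells called diploid")
        return out
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    lab = gm.fit_predict(x)
    one = GaussianMixture(n_components=1, random_state=seed)
    one.fit(x)
    if one.bic(x) <= gm.bic(x):
        warnings.warn("signal variance is unimodal; all cells called diploid")
        return out
    means = gm.means_.ravel()
    if abs(means[0] - means[1]) < 1e-3:
        warnings.warn("mixture components indistinguishable; all cells called diploid")
        return out
    out[np.flatnonzero(cand)] = lab == int(np.argmax(means))
    return out


def consensus_union(call_a: np.ndarray, call_b: np.ndarray) -> np.ndarray:
    """A cell is malignant when either caller flags it."""
    call_a, call_b = np.asarray(call_a, bool), np.asarray(call_b, bool)
    if call_a.shape != call_b.shape:
        raise ValueError("caller outputs cover different cell universes")
    return call_a | call_b


def spike_reference(
    analysis_mask: np.ndarray,
    epithelial_mask: np.ndarray,
    normal_pool_mask: np.ndarray,
    params: CnvParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Keep the epithelial share of the CNV input below the configured cap.

    When epithelial cells exceed ``max_reference_epithelial_fraction`` of
    the analyzed cells, additional normal-profile cells are drawn (without
    replacement) from the provided pool and added, which dilutes the
    epithelial fraction. Returns an updated inclusion mask.
    """
    include = analysis_mask.copy()
    frac = epithelial_mask[include].mean() if include.any() else 0.0
    pool = np.flatnonzero(normal_pool_mask & ~include)
    if frac <= params.max_reference_epithelial_fraction or len(pool) == 0:
        return include
    n_epi = int((epithelial_mask & include).sum())
    target_total = int(np.ceil(n_epi / params.max_reference_epithelial_fraction))
    n_add = min(target_total - int(include.sum()), len(pool))
    if n_add > 0:
        include[rng.choice(pool, size=n_add, replace=False)] = True
    return include


def run_cnv_stage(
    norm: NormalizedMatrix,
    raw_counts: np.ndarray,
    lineage: pd.Series,
    positions: GenePositionTable,
    params: CnvParams | None = None,
    seed: int = 0,
) -> CnvProfileMatrix:
    """Full CNV stage: order genes, infer signal, summarize, call consensus."""
    params = params or CnvParams()
    reference = lineage.isin(REFERENCE_LINEAGES).to_numpy()
    candidate = (lineage == "Epithelial").to_numpy()
    order = build_genomic_order(positions, norm.gene_ids, params.exclude_chromosomes)
    profile = infer_cnv_signal(
        norm, reference, order, params, candidate_mask=candidate, raw_counts=raw_counts
    )
    summary = summarize_cnv_cells(profile, params)
    thr = call_malignant_threshold(summary, candidate, params)
    aneu = aneuploid_cluster_call(profile, seed=seed)
    consensus = consensus_union(thr, aneu)
    profile.calls = pd.DataFrame(
        {
            "threshold_call": thr,
            "aneuploid_call": aneu,
            "consensus_call": consensus,
            "candidate": candidate,
        },
        index=profile.cell_barcodes,
    )
    log.info(
        "CNV calls: %d/%d candidates malignant (threshold %d, aneuploid %d)",
        int(consensus.sum()), int(candidate.sum()), int(thr.sum()), int(aneu.sum()),
    )
    return profile
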