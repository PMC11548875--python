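"""Tumor-cell signature discovery on malignant cells.

Four signature families are produced: Wilcoxon DEG sets with the four-way
filter (|logFC| > 0.25, p < 0.01, Bonferroni-adjusted p < 0.01, pct > 0.25)
combined into INT/UNION sets over the three response comparisons; rank-30
NMF programs with group assignment by relative loading share and Fisher
odds-ratio enrichment; top-coefficient gene modules; and PC1-10 pos/neg
signatures. Signatures score per sample as the malignant-cell mean of the
signature-gene mean expression, max-normalized across samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from scipy.stats import rankdata

from .config import DegThresholds, NmfParams, PcaSigParams
from .qc import NormalizedMatrix, ScaledMatrix

log = logging.getLogger(__name__)


@dataclass
class GeneSignature:
    name: str
    genes: tuple[str, ...]
    direction: str = "neutral"  # up / down / neutral
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} has duplicate genes")


# --------------------------------------------------------------------------
# differential expression


def _wilcoxon_p_vectorized(values: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Two-tailed rank-sum p per gene (rows), normal approximation with tie
    correction and continuity correction."""
    n = values.shape[1]
    n1 = int(mask_a.sum())
    n2 = n - n1
    ranks = rankdata(values, axis=1)
    r1 = ranks[:, mask_a].sum(axis=1)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, cnt = np.unique(values[i], return_counts=True)
        tie_term[i] = (cnt**3 - cnt).sum()
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 1e-300))
    z = (np.abs(u1 - mu) - 0.5) / sigma
    z = np.maximum(z, 0.0)
    return np.minimum(2 * scipy.stats.norm.sf(z), 1.0)


def _wilcoxon_p_single(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-tailed rank-sum p when both groups are small and tie-free."""
    if len(a) <= 8 and len(b) <= 8 and len(np.unique(np.r_[a, b])) == len(a) + len(b):
        return float(scipy.stats.mannwhitneyu(a, b, method="exact").pvalue)
    vals = np.r_[a, b][None, :]
    mask = np.zeros(len(a) + len(b), bool)
    mask[: len(a)] = True
    return float(_wilcoxon_p_vectorized(vals, mask)[0])


def wilcoxon_deg(
    norm: NormalizedMatrix,
    counts: np.ndarray,
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    thresholds: DegThresholds | None = None,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum DE between two cell groups.

    logFC is the difference of group means of log-normalized expression
    (positive = higher in group A); pct is the fraction of cells with a
    raw count > 0. Genes reach testing only when |logFC| exceeds the
    threshold and pct does in at least one group; Bonferroni runs over the
    genes actually tested. The returned frame has a ``pass_filter`` column
    and an ``up`` flag for genes higher in group A.
    """
    thresholds = thresholds or DegThresholds()
    cells_a, cells_b = np.asarray(cells_a), np.asarray(cells_b)
    if cells_a.dtype == bool:
        cells_a = np.flatnonzero(cells_a)
    if cells_b.dtype == bool:
        cells_b = np.flatnonzero(cells_b)
    if np.intersect1d(cells_a, cells_b).size:
        raise ValueError("cell groups overlap")
    if len(cells_a) < 3 or len(cells_b) < 3:
        raise ValueError("both groups need >= 3 cells")

    counts = np.asarray(counts)
    pct_a = (counts[:, cells_a] > 0).mean(axis=1)
    pct_b = (counts[:, cells_b] > 0).mean(axis=1)
    va, vb = norm.values[:, cells_a], norm.values[:, cells_b]
    logfc = va.mean(axis=1) - vb.mean(axis=1)

    tested = (np.abs(logfc) > thresholds.min_abs_logfc) & (
        (pct_a >= thresholds.min_pct) | (pct_b >= thresholds.min_pct)
    )
    p = np.full(len(logfc), np.nan)
    t_idx = np.flatnonzero(tested)
    if len(t_idx):
        both = np.concatenate([va[t_idx], vb[t_idx]], axis=1)
        mask_a = np.zeros(both.shape[1], bool)
        mask_a[: len(cells_a)] = True
        if len(cells_a) <= 8 and len(cells_b) <= 8:
            p[t_idx] = [
                _wilcoxon_p_single(va[i], vb[i]) for i in t_idx
            ]
        else:
            p[t_idx] = _wilcoxon_p_vectorized(both, mask_a)
    adj_p = np.minimum(p * len(t_idx), 1.0)
    passed = (
        tested
        & (p < thresholds.max_p)
        & (adj_p < thresholds.max_adj_p)
    )
    return pd.DataFrame(
        {
            "gene": np.asarray(norm.gene_ids),
            "logfc": logfc,
            "p": p,
            "adj_p": adj_p,
            "pct_a": pct_a,
            "pct_b": pct_b,
            "tested": tested,
            "pass_filter": passed,
            "up": passed & (logfc > 0),
        }
    ).set_index("gene")


def deg_sets(table: pd.DataFrame) -> tuple[set[str], set[str]]:
    up = set(table.index[table["pass_filter"] & (table["logfc"] > 0)])
    down = set(table.index[table["pass_filter"] & (table["logfc"] < 0)])
    return up, down


def build_int_union(deg_tables: list[pd.DataFrame]) -> dict[str, GeneSignature]:
    """INT/UNION of up- and downregulated genes across the three comparisons
    (responder vs non-responder, PR vs PD, PR vs SD; group A = responder/PR
    side throughout, so 'up' means higher in responders)."""
    if len(deg_tables) < 3:
        raise ValueError("need the three response comparisons")
    ups, downs = zip(*(deg_sets(t) for t in deg_tables))
    out: dict[str, GeneSignature] = {}
    for name, sets, direction in (
        ("INT.up", ups, "up"),
        ("INT.down", downs, "down"),
        ("UNION.up", ups, "up"),
        ("UNION.down", downs, "down"),
    ):
        if name.startswith("INT"):
            genes = set.intersection(*sets)
        else:
            genes = set.union(*sets)
        if not genes:
            warnings.warn(f"{name} is empty")
            continue
        out[name] = GeneSignature(
            name, tuple(sorted(genes)), direction, provenance="deg:3-comparisons"
        )
    return out


# --------------------------------------------------------------------------
# NMF


@dataclass
class NmfModel:
    W: np.ndarray  # genes x rank
    H: np.ndarray  # rank x cells
    errors: list[float]
    gene_ids: pd.Index
    cell_barcodes: pd.Index

    @property
    def rank(self) -> int:
        return self.W.shape[1]


def fit_nmf(
    matrix: np.ndarray,
    params: NmfParams | None = None,
    gene_ids: pd.Index | None = None,
    cell_barcodes: pd.Index | None = None,
    seed: int = 0,
) -> NmfModel:
    """Frobenius NMF by multiplicative updates.

    Seeded uniform initialization; iteration stops at ``max_iter`` or when
    the relative error change falls below ``tol``. Factors come out ordered
    by total loading (descending, ties by original index), so the model is
    deterministic for a given seed.
    """
    params = params or NmfParams()
    V = np.asarray(matrix, dtype=float)
    if np.any(V < 0):
        raise ValueError("NMF input must be non-negative")
    n_genes, n_cells = V.shape
    rank = min(params.rank, n_genes, n_cells)
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / rank) if V.mean() > 0 else 1.0
    W = rng.uniform(1e-4, 1.0, (n_genes, rank)) * scale
    H = rng.uniform(1e-4, 1.0, (rank, n_cells)) * scale
    eps = 1e-10
    norm_v = np.linalg.norm(V)
    errors: list[float] = []
    for _ in range(params.max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        err = np.linalg.norm(V - W @ H) / (norm_v + eps)
        if errors and errors[-1] - err < params.tol * errors[-1]:
            errors.append(err)
            break
        errors.append(err)
    total = W.sum(axis=0) * H.sum(axis=1)
    order = np.lexsort((np.arange(rank), -total))
    return NmfModel(
        W=W[:, order],
        H=H[order],
        errors=errors,
        gene_ids=pd.Index(gene_ids) if gene_ids is not None else pd.RangeIndex(n_genes),
        cell_barcodes=pd.Index(cell_barcodes)
        if cell_barcodes is not None
        else pd.RangeIndex(n_cells),
    )


def derive_nmf_programs(
    model: NmfModel,
    group_labels: pd.Series | np.ndarray,
    params: NmfParams | None = None,
) -> tuple[pd.DataFrame, dict[str, GeneSignature]]:
    """Assign factors to RECIST groups by relative loading share.

    share(f, g) is factor f's mean per-cell loading in group g, normalized
    across groups to sum to 1. A factor joins group g* = argmax share when
    its share clears (1/G)(1 + margin); otherwise it stays unassigned. Each
    group's program signature is the union of its member factors' top
    ``top_genes_per_factor`` genes by W.
    """
    params = params or NmfParams()
    groups = pd.Series(np.asarray(group_labels), index=model.cell_barcodes)
    if groups.isna().any():
        raise ValueError("missing group labels: a group with no cells is undefined")
    names = sorted(groups.unique())
    shares = np.zeros((model.rank, len(names)))
    for j, g in enumerate(names):
        mask = (groups == g).to_numpy()
        if not mask.any():
            raise ValueError(f"group {g!r} has no cells")
        if params.share_normalization == "mean":
            shares[:, j] = model.H[:, mask].mean(axis=1)
        else:
            shares[:, j] = model.H[:, mask].sum(axis=1)
    shares /= np.maximum(shares.sum(axis=1, keepdims=True), 1e-300)
    cut = (1.0 / len(names)) * (1.0 + params.assignment_margin)
    assigned = np.where(shares.max(axis=1) > cut, np.argmax(shares, axis=1), -1)
    share_table = pd.DataFrame(
        shares, columns=names, index=[f"factor{i + 1}" for i in range(model.rank)]
    )
    share_table["assigned_group"] = [names[a] if a >= 0 else "" for a in assigned]

    signatures: dict[str, GeneSignature] = {}
    for j, g in enumerate(names):
        members = np.flatnonzero(assigned == j)
        if not len(members):
            continue
        genes: set[str] = set()
        for f in members:
            top = np.lexsort((np.arange(len(model.gene_ids)), -model.W[:, f]))[
                : params.top_genes_per_factor
            ]
            genes |= set(model.gene_ids[top])
        signatures[f"NMF.{g}"] = GeneSignature(
            f"NMF.{g}", tuple(sorted(genes)), "up",
            provenance="factors:" + ",".join(str(f + 1) for f in members),
        )
    return share_table, signatures


def refine_top_gene_modules(
    coefficient_tables: dict[str, pd.Series],
    module_groups: dict[str, str],
    top_n: int = 100,
) -> dict[str, GeneSignature]:
    """Per-group union of each member module's top-N coefficient genes.

    Ties break by ascending gene index; modules shorter than N are taken
    whole with a warning.
    """
    per_group: dict[str, set[str]] = {}
    for mod, coefs in coefficient_tables.items():
        if len(coefs) < top_n:
            warnings.warn(f"module {mod!r} has only {len(coefs)} genes (< {top_n})")
        order = np.lexsort((np.arange(len(coefs)), -coefs.to_numpy()))
        top = set(coefs.index[order[:top_n]])
        per_group.setdefault(module_groups[mod], set()).update(top)
    return {
        f"module.{g}": GeneSignature(
            f"module.{g}", tuple(sorted(genes)), "up", provenance=f"modules:{g}"
        )
        for g, genes in per_group.items()
    }


# --------------------------------------------------------------------------
# enrichment


def fisher_odds_ratio(table: np.ndarray) -> tuple[float, float]:
    """(odds ratio, Fisher exact p) for a 2x2 table, with Haldane-Anscombe
    0.5 correction on the OR whenever any cell is zero."""
    table = np.asarray(table, dtype=float)
    a, b, c, d = table.ravel()
    p = float(scipy.stats.fisher_exact(table.astype(int))[1])
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a * d / (b * c)), p


def assign_cells_to_programs(
    norm: NormalizedMatrix, signatures: dict[str, GeneSignature]
) -> pd.Series:
    """Each cell joins its argmax-scoring program (mean z-scored expression
    of the signature genes; z across cells)."""
    if not signatures:
        raise ValueError("no signatures to assign")
    z = norm.values - norm.values.mean(axis=1, keepdims=True)
    sd = norm.values.std(axis=1, ddof=0)
    z /= np.where(sd > 0, sd, 1.0)[:, None]
    names = list(signatures)
    scores = np.zeros((len(names), norm.values.shape[1]))
    for i, name in enumerate(names):
        idx = norm.gene_ids.get_indexer(
            [g for g in signatures[name].genes if g in norm.gene_ids]
        )
        scores[i] = z[idx].mean(axis=0)
    return pd.Series(
        np.array(names)[scores.argmax(axis=0)], index=norm.cell_barcodes
    )


def enrichment_odds_ratio(
    cell_program: pd.Series, group_labels: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Per (program, group) 2x2 Fisher test of program membership vs group
    membership, plus a per-program z-transformed log-OR across groups."""
    groups = pd.Series(np.asarray(group_labels), index=cell_program.index)
    group_names = sorted(groups.unique())
    if len(group_names) < 2:
        raise ValueError("enrichment needs at least two groups")
    rows = []
    for prog in sorted(cell_program.unique()):
        in_prog = cell_program == prog
        for g in group_names:
            in_g = groups == g
            tab = np.array(
                [
                    [(in_prog & in_g).sum(), (in_prog & ~in_g).sum()],
                    [(~in_prog & in_g).sum(), (~in_prog & ~in_g).sum()],
                ]
            )
            oratio, p = fisher_odds_ratio(tab)
            rows.append((prog, g, oratio, p))
    out = pd.DataFrame(rows, columns=["program", "group", "odds_ratio", "p"])
    out["log_or"] = np.log(out["odds_ratio"])
    z = out.groupby("program")["log_or"].transform(
        lambda s: (s - s.mean()) / s.std(ddof=0) if s.std(ddof=0) > 0 else 0.0
    )
    out["z_or"] = z
    return out


# --------------------------------------------------------------------------
# PCA signatures


def pca_signatures(
    scaled: ScaledMatrix, params: PcaSigParams | None = None
) -> tuple[dict[str, GeneSignature], np.ndarray]:
    """PC1..n pos/neg signatures from an SVD of the scaled HVG matrix.

    The per-PC sign is fixed by making the largest-magnitude gene loading
    positive, which makes the output deterministic across runs and cell
    permutations. Returns the signatures and the gene loading matrix.
    """
    params = params or PcaSigParams()
    X = scaled.values  # genes x cells, already gene-centered by scaling
    if X.shape[0] < 2 * params.top_genes:
        raise ValueError(
            f"need >= {2 * params.top_genes} genes for {params.top_genes}-gene signatures"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    U, s, _ = scipy.linalg.svd(Xc, full_matrices=False)
    n_pcs = min(params.n_pcs, U.shape[1])
    loadings = U[:, :n_pcs]
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_pcs)])
    loadings = loadings * flip[None, :]
    out: dict[str, GeneSignature] = {}
    gene_arr = np.asarray(scaled.gene_ids)
    for k in range(n_pcs):
        order = np.lexsort((np.arange(len(gene_arr)), -loadings[:, k]))
        pos = gene_arr[order[: params.top_genes]]
        neg = gene_arr[order[-params.top_genes :]][::-1]
        out[f"PC{k + 1}.pos"] = GeneSignature(
            f"PC{k + 1}.pos", tuple(pos), "up", provenance=f"pc:{k + 1}"
        )
        out[f"PC{k + 1}.neg"] = GeneSignature(
            f"PC{k + 1}.neg", tuple(neg), "down", provenance=f"pc:{k + 1}"
        )
    return out, loadings


# --------------------------------------------------------------------------
# scoring


def score_signature_per_sample(
    norm: NormalizedMatrix,
    signature: GeneSignature,
    malignant_mask: np.ndarray,
    sample_ids: pd.Series | np.ndarray,
) -> pd.Series:
    """Per-sample malignant-cell mean of the signature-gene mean expression,
    divided by the maximum across samples. Samples without malignant cells
    get NaN."""
    present = [g for g in signature.genes if g in norm.gene_ids]
    if not present:
        raise ValueError(f"signature {signature.name!r} absent from matrix")
    idx = norm.gene_ids.get_indexer(present)
    cell_score = norm.values[idx].mean(axis=0)
    samples = pd.Series(np.asarray(sample_ids), index=norm.cell_barcodes)
    mask = np.asarray(malignant_mask, dtype=bool)
    per_sample = (
        pd.Series(cell_score[mask], index=samples[mask].to_numpy())
        .groupby(level=0)
        .mean()
    )
    per_sample = per_sample.reindex(sorted(samples.unique()))
    if per_sample.isna().any():
        warnings.warn(
            f"samples without malignant cells: {list(per_sample.index[per_sample.isna()])}"
        )
    mx = per_sample.max()
    return per_sample / mx if mx and mx > 0 else per_sample
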