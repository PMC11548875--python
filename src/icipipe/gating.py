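"""ADT-assisted partition of T/NK cells into CD4+ T, CD8+ T and NK.

Gating proceeds in three steps: a CD3 RNA gate (any of CD3D/CD3E/CD3G
detected), an ADT percentile gate separating CD4 from CD8 among CD3+ cells,
and an NK RNA-marker gate among CD3- cells. Cells without a confident gate
are labeled by a PCA + multinomial-logistic classifier trained on the gated
cells, with a reject option below a probability threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .config import AdtGateParams
from .qc import NormalizedMatrix, ScaledMatrix

log = logging.getLogger(__name__)

LABELS = ("CD4T", "CD8T", "NK")


@dataclass
class TnkLabels:
    """Final per-cell T/NK partition with provenance."""

    table: pd.DataFrame  # label, source (gate|classifier), probability

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    def ambiguous_fraction(self) -> float:
        return float((self.table["label"] == "ambiguous").mean())


def gate_cd3(
    counts: np.ndarray, gene_ids: pd.Index, params: AdtGateParams | None = None
) -> np.ndarray:
    """CD3+ iff any of the CD3 complex genes has a raw count > 0."""
    params = params or AdtGateParams()
    present = [g for g in params.cd3_genes if g in gene_ids]
    if not present:
        raise ValueError(f"none of {params.cd3_genes} in the gene universe")
    idx = gene_ids.get_indexer(present)
    return (np.asarray(counts)[idx] > 0).any(axis=0)


def clr_transform(adt: pd.DataFrame) -> pd.DataFrame:
    """Centered log-ratio per cell: log1p counts minus their per-cell mean."""
    logged = np.log1p(adt.to_numpy(dtype=float))
    return pd.DataFrame(
        logged - logged.mean(axis=0, keepdims=True), index=adt.index, columns=adt.columns
    )


def gate_adt_lineage(
    adt: pd.DataFrame, cd3_mask: np.ndarray, params: AdtGateParams | None = None
) -> pd.Series:
    """Per-marker percentile gate over CD3+ cells.

    A cell is marker-positive when its (CLR-transformed) ADT level is
    strictly above the marker's 55th percentile among CD3+ cells. CD4-only
    positives are CD4T, CD8-only CD8T, dual positives ambiguous, dual
    negatives unassigned. CD3- cells are not gated (NA).
    """
    params = params or AdtGateParams()
    for m in (params.cd4_marker, params.cd8_marker):
        if m not in adt.index:
            raise ValueError(f"ADT table lacks required marker {m!r}")
    values = clr_transform(adt) if params.adt_transform == "clr" else adt.astype(float)
    cd3_mask = np.asarray(cd3_mask, dtype=bool)
    out = pd.Series(pd.NA, index=adt.columns, dtype="object")
    if not cd3_mask.any():
        return out
    pos = {}
    for m in (params.cd4_marker, params.cd8_marker):
        v = values.loc[m].to_numpy()
        cut = np.percentile(v[cd3_mask], params.adt_percentile)
        pos[m] = v > cut
    cd4, cd8 = pos[params.cd4_marker], pos[params.cd8_marker]
    lab = np.where(
        cd4 & ~cd8, "CD4T", np.where(cd8 & ~cd4, "CD8T", np.where(cd4 & cd8, "ambiguous", "unassigned"))
    )
    out[cd3_mask] = lab[cd3_mask]
    return out


def gate_nk(
    norm: NormalizedMatrix, cd3_mask: np.ndarray, params: AdtGateParams | None = None
) -> np.ndarray:
    """NK iff a CD3- cell's mean NK-marker expression clears the percentile cutoff.

    The cutoff mirrors the ADT convention: the 55th percentile of the same
    score among CD3- cells, strict inequality.
    """
    params = params or AdtGateParams()
    present = [g for g in params.nk_marker_genes if g in norm.gene_ids]
    if not present:
        raise ValueError(f"no NK marker gene ({params.nk_marker_genes}) in the gene universe")
    cd3_mask = np.asarray(cd3_mask, dtype=bool)
    score = norm.values[norm.gene_ids.get_indexer(present)].mean(axis=0)
    out = np.zeros(len(score), dtype=bool)
    neg = ~cd3_mask
    if neg.any():
        cut = np.percentile(score[neg], params.adt_percentile)
        out[neg] = score[neg] > cut
    return out


def train_and_classify(
    reference_labels: pd.Series,
    scaled: ScaledMatrix,
    query_cells: np.ndarray,
    params: AdtGateParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Propagate gate labels to ungated cells.

    Reference and query are projected into the reference's top principal
    components; a regularized multinomial logistic model supplies class
    probabilities, and a query cell keeps its argmax label only when that
    probability reaches the threshold, otherwise it stays ambiguous.
    """
    params = params or AdtGateParams()
    ref = reference_labels.dropna()
    counts = ref.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two reference classes")
    small = counts[counts < params.min_reference_cells]
    if len(small):
        raise ValueError(
            f"reference class(es) below {params.min_reference_cells} cells: "
            f"{dict(small)} — review gate thresholds"
        )
    X = scaled.values.T  # cells x genes
    barcodes = pd.Index(scaled.cell_barcodes)
    ref_idx = barcodes.get_indexer(ref.index)
    n_pcs = min(params.n_pcs, len(ref_idx) - 1, X.shape[1])
    pca = PCA(n_components=n_pcs, svd_solver="randomized", random_state=seed)
    ref_pcs = pca.fit_transform(X[ref_idx])
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(ref_pcs, ref.to_numpy())
    query_idx = barcodes.get_indexer(pd.Index(query_cells))
    if (query_idx < 0).any():
        raise ValueError("query cells missing from scaled matrix")
    probs = clf.predict_proba(pca.transform(X[query_idx]))
    best = probs.argmax(axis=1)
    best_p = probs[np.arange(len(best)), best]
    label = np.where(
        best_p >= params.unassigned_prob_threshold, clf.classes_[best], "ambiguous"
    )
    return pd.DataFrame(
        {"label": label, "probability": best_p}, index=pd.Index(query_cells)
    )


def assign_tnk(
    counts: np.ndarray,
    norm: NormalizedMatrix,
    scaled: ScaledMatrix,
    adt: pd.DataFrame,
    params: AdtGateParams | None = None,
    seed: int = 0,
) -> TnkLabels:
    """Full partition of the given T/NK cells into CD4T/CD8T/NK/ambiguous."""
    params = params or AdtGateParams()
    barcodes = pd.Index(norm.cell_barcodes)
    cd3 = gate_cd3(counts, norm.gene_ids, params)
    adt_lab = gate_adt_lineage(adt, cd3, params)
    nk = gate_nk(norm, cd3, params)

    label = pd.Series("ambiguous", index=barcodes, dtype="object")
    source = pd.Series("classifier", index=barcodes, dtype="object")
    prob = pd.Series(np.nan, index=barcodes)
    gated = adt_lab.isin(["CD4T", "CD8T"]).to_numpy()
    label[gated] = adt_lab[gated]
    label[nk] = "NK"
    source[gated | nk] = "gate"
    prob[gated | nk] = 1.0

    query = barcodes[~(gated | nk)]
    if len(query):
        ref = label[gated | nk]
        res = train_and_classify(ref, scaled, query.to_numpy(), params, seed=seed)
        label[res.index] = res["label"]
        prob[res.index] = res["probability"]
    table = pd.DataFrame({"label": label, "source": source, "probability": prob})
    out = TnkLabels(table)
    log.info(
        "T/NK gating: %s; ambiguous fraction %.3f",
        dict(table["label"].value_counts()), out.ambiguous_fraction(),
    )
    return out
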