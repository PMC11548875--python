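"""TCR/BCR clonotype calling, clone-size classes and functional scores.

Clonotypes require a complete chain pair (TRA+TRB for TCR, IGH plus IGK or
IGL for BCR) and are keyed by both chains' V(D)JC genes plus CDR3
nucleotide sequence (the "gene+nt" rule). Clone sizes classify into
Single/Small/Medium/Large/Hyperexpanded by the standard upper bounds
1/5/10/20/inf, and relative clone size divides by the compartment's paired
cells within the same sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import genesets
from .config import CloneSizeBins
from .qc import NormalizedMatrix, score_gene_set

log = logging.getLogger(__name__)

_PAIRING = {
    "TCR": (("TRA",), ("TRB",)),
    "BCR": (("IGH",), ("IGK", "IGL")),
}

FUNCTIONAL_SETS = {
    "regulatory": genesets.REGULATORY_GENES,
    "cytotoxic": genesets.CYTOTOXIC_GENES,
}


def _best_contigs(contigs: pd.DataFrame, chains: tuple[str, ...]) -> pd.DataFrame:
    """One contig per cell for a chain side: highest UMI count wins, ties
    break by lexicographic CDR3 nucleotide sequence."""
    sub = contigs[contigs["chain"].isin(chains)]
    return (
        sub.sort_values(["umis", "cdr3_nt"], ascending=[False, True], kind="stable")
        .drop_duplicates("barcode", keep="first")
        .set_index("barcode")
    )


def call_clonotypes(
    contigs: pd.DataFrame,
    receptor: str,
    cell_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One row per paired cell: clonotype_id plus the chain fields.

    Cells lacking a complete pair are silently excluded (count logged).
    When a cell carries more than one contig for a chain side, the
    highest-UMI contig is used.
    """
    if receptor not in _PAIRING:
        raise ValueError(f"receptor must be TCR or BCR, got {receptor!r}")
    first, second = _PAIRING[receptor]
    contigs = contigs.copy()
    if "umis" not in contigs:
        contigs["umis"] = 1
    side_1 = _best_contigs(contigs, first)
    side_2 = _best_contigs(contigs, second)
    paired = side_1.join(side_2, how="inner", lsuffix="_1", rsuffix="_2")
    relevant = contigs[contigs["chain"].isin(first + second)]
    n_unpaired = relevant["barcode"].nunique() - len(paired)
    if n_unpaired:
        log.info("%s: %d cell(s) without a complete chain pair excluded", receptor, n_unpaired)
    key_cols = [
        f"{f}_{i}"
        for i in (1, 2)
        for f in ("chain", "v_gene", "d_gene", "j_gene", "c_gene", "cdr3_nt")
    ]
    if not len(paired):
        return pd.DataFrame(columns=key_cols + ["clonotype_id"])

    key = paired[key_cols].astype(str).agg("|".join, axis=1)
    codes, _ = pd.factorize(key, sort=True)
    out = paired[key_cols].copy()
    out["clonotype_id"] = [f"{receptor}_cl{c + 1:05d}" for c in codes]
    if cell_meta is not None:
        out = out.join(cell_meta, how="left")
    return out


def classify_clone_sizes(
    table: pd.DataFrame,
    bins: CloneSizeBins | None = None,
    compartment: pd.Series | None = None,
    sample_id: pd.Series | None = None,
) -> pd.DataFrame:
    """Clone size, size class and relative clone size per cell.

    Size counts cells sharing the clonotype id; the relative size divides
    by the total number of paired cells in the cell's compartment (within
    its sample when sample ids are given).
    """
    bins = bins or CloneSizeBins()
    out = table.copy()
    out["clone_size"] = out.groupby("clonotype_id")["clonotype_id"].transform("size")
    out["size_class"] = classify_sizes(out["clone_size"].to_numpy(), bins)
    if compartment is not None:
        out["compartment"] = compartment.reindex(out.index)
    if "compartment" not in out:
        out["compartment"] = "all"
    if sample_id is not None:
        out["sample_id"] = sample_id.reindex(out.index)
    keys = ["compartment"] + (["sample_id"] if "sample_id" in out else [])
    totals = out.groupby(keys)["clonotype_id"].transform("size")
    out["relative_clone_size"] = out["clone_size"] / totals
    return out


def classify_sizes(sizes: np.ndarray, bins: CloneSizeBins | None = None) -> np.ndarray:
    """Map clone sizes to class names by half-open upper bounds (n <= bound)."""
    bins = bins or CloneSizeBins()
    sizes = np.asarray(sizes)
    if (sizes < 1).any():
        raise ValueError("clone sizes must be >= 1")
    names = [n for n, _ in bins.bounds]
    bounds = [b for _, b in bins.bounds]
    idx = np.searchsorted(bounds, sizes, side="left")
    return np.array(names, dtype=object)[idx]


def functional_scores(
    norm: NormalizedMatrix,
    gene_sets: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Per-cell mean log-normalized expression of each functional gene set."""
    gene_sets = gene_sets or FUNCTIONAL_SETS
    return pd.DataFrame(
        {name: score_gene_set(norm, genes) for name, genes in gene_sets.items()},
        index=norm.cell_barcodes,
    )
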