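"""In-memory containers shared by every stage.

``CellCohort`` carries the gene x cell UMI matrix together with the ADT
counts, per-cell and per-sample metadata; it is the object each stage
consumes and annotates. ``GenePositionTable`` orders genes along the genome
for the CNV stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: RECIST category -> binary response class used throughout. Partial
#: response counts as responder; stable and progressive disease are
#: non-responders (no complete responses in the cohort model).
RECIST_TO_RESPONSE = {"PR": "responder", "SD": "non-responder", "PD": "non-responder"}

VALID_CHAINS = {"TRA", "TRB", "IGH", "IGK", "IGL"}


@dataclass
class CellCohort:
    counts: np.ndarray  # genes x cells, non-negative ints
    gene_ids: pd.Index
    cell_barcodes: pd.Index
    cell_meta: pd.DataFrame  # indexed by barcode
    sample_meta: pd.DataFrame  # indexed by sample_id
    adt: pd.DataFrame | None = None  # markers x cells

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_barcodes = pd.Index(self.cell_barcodes)
        self.validate()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_barcodes)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_barcodes)} cells"
            )
        if self.cell_barcodes.has_duplicates:
            dup = self.cell_barcodes[self.cell_barcodes.duplicated()][0]
            raise ValueError(f"duplicate cell barcode: {dup!r}")
        if len(self.cell_meta) != len(self.cell_barcodes):
            raise ValueError("cell_meta rows must match cell_barcodes")
        if "sample_id" in self.cell_meta:
            missing = set(self.cell_meta["sample_id"]) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"cell_meta sample_ids missing from sample_meta: {sorted(missing)}")
        if self.adt is not None and self.adt.shape[1] != len(self.cell_barcodes):
            raise ValueError("adt columns must match cell_barcodes")
        if {"recist", "response"} <= set(self.sample_meta.columns):
            want = self.sample_meta["recist"].map(RECIST_TO_RESPONSE)
            bad = self.sample_meta.index[want != self.sample_meta["response"]]
            if len(bad):
                raise ValueError(f"RECIST/response inconsistent for samples: {list(bad)}")

    def subset_cells(self, mask: np.ndarray) -> "CellCohort":
        """Return a new cohort restricted to cells where ``mask`` is True."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellCohort(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids,
            cell_barcodes=self.cell_barcodes[idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            sample_meta=self.sample_meta,
            adt=None if self.adt is None else self.adt.iloc[:, idx],
        )


@dataclass
class GenePositionTable:
    """Genomic coordinates (1-based, inclusive) for ordering genes."""

    table: pd.DataFrame  # columns gene_id, chromosome, start, end
    chromosome_order: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        required = {"gene_id", "chromosome", "start", "end"}
        if not required <= set(self.table.columns):
            raise ValueError(f"gene position table needs columns {sorted(required)}")
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene start must be <= end")
        if not self.chromosome_order:
            self.chromosome_order = tuple(pd.unique(self.table["chromosome"]))
        unknown = set(self.table["chromosome"]) - set(self.chromosome_order)
        if unknown:
            raise ValueError(f"chromosomes outside declared order: {sorted(unknown)}")
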