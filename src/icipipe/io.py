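"""Readers and writers for the on-disk formats.

Count matrices travel as the 10x Cell Ranger triplet (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv``, optionally gzipped; genes as rows,
1-based Matrix Market indices). Metadata, contigs and all result tables are
headered CSV/TSV so everything is diffable.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .cohort import VALID_CHAINS, CellCohort, GenePositionTable

CONTIG_COLUMNS = ["barcode", "chain", "v_gene", "d_gene", "j_gene", "c_gene", "cdr3_nt"]


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {dir_path}")


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_counts_mtx(dir_path: str | Path) -> tuple[np.ndarray, pd.Index, pd.Index]:
    """Read a 10x triplet directory -> (dense counts, gene_ids, barcodes).

    Raises on a header/triplet dimension mismatch (via the Matrix Market
    parser) and on duplicate barcodes, naming the offender.
    """
    dir_path = Path(dir_path)
    mat = scipy.io.mmread(_find(dir_path, "matrix.mtx"))
    counts = np.asarray(sp.coo_matrix(mat).todense())
    barcodes = pd.Index(_read_lines(_find(dir_path, "barcodes.tsv")))
    features = [line.split("\t")[0] for line in _read_lines(_find(dir_path, "features.tsv"))]
    gene_ids = pd.Index(features)
    if counts.shape != (len(gene_ids), len(barcodes)):
        raise ValueError(
            f"matrix is {counts.shape} but features/barcodes give "
            f"{len(gene_ids)} x {len(barcodes)}"
        )
    if barcodes.has_duplicates:
        dup = barcodes[barcodes.duplicated()][0]
        raise ValueError(f"duplicate cell barcode: {dup!r}")
    return counts, gene_ids, barcodes


def write_counts_mtx(
    dir_path: str | Path, counts: np.ndarray, gene_ids: pd.Index, barcodes: pd.Index
) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(np.asarray(counts))
    scipy.io.mmwrite(dir_path / "matrix.mtx", coo, field="integer")
    (dir_path / "barcodes.tsv").write_text("".join(f"{b}\n" for b in barcodes))
    (dir_path / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in gene_ids)
    )


def read_vdj_contigs(csv_path: str | Path) -> pd.DataFrame:
    """Parse a 10x filtered-contig-annotations style CSV.

    One row per contig; ``d_gene`` may be the string "None" (alpha/light
    chains have no D segment) and is mapped to the empty string. Unknown
    chain values and missing required columns are hard errors.
    """
    df = pd.read_csv(csv_path, dtype=str).fillna("None")
    missing = [c for c in CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"contig CSV missing required columns: {missing}")
    if len(df):
        bad = set(df["chain"]) - VALID_CHAINS
        if bad:
            raise ValueError(f"unknown chain value(s): {sorted(bad)}")
    df["d_gene"] = df["d_gene"].replace("None", "")
    if "umis" in df.columns:
        df["umis"] = pd.to_numeric(df["umis"]).astype(int)
    else:
        df["umis"] = 1
    return df


def write_vdj_contigs(csv_path: str | Path, contigs: pd.DataFrame) -> None:
    out = contigs.copy()
    out["d_gene"] = out["d_gene"].replace("", "None")
    out.to_csv(csv_path, index=False)


def read_gene_positions(path: str | Path, chromosome_order=None) -> GenePositionTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    return GenePositionTable(
        df, chromosome_order=tuple(chromosome_order) if chromosome_order else ()
    )


def write_gene_positions(path: str | Path, positions: GenePositionTable) -> None:
    positions.table.to_csv(path, sep="\t", index=False)


def write_cohort(dir_path: str | Path, cohort: CellCohort) -> None:
    """Write a cohort as the 10x triplet plus ADT/metadata CSVs."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    write_counts_mtx(dir_path, cohort.counts, cohort.gene_ids, cohort.cell_barcodes)
    cohort.cell_meta.to_csv(dir_path / "cell_meta.csv", index_label="barcode")
    cohort.sample_meta.to_csv(dir_path / "sample_meta.csv", index_label="sample_id")
    if cohort.adt is not None:
        cohort.adt.to_csv(dir_path / "adt.csv", index_label="marker")


def read_cohort(dir_path: str | Path) -> CellCohort:
    dir_path = Path(dir_path)
    counts, gene_ids, barcodes = read_counts_mtx(dir_path)
    cell_meta = pd.read_csv(dir_path / "cell_meta.csv", index_col="barcode")
    sample_meta = pd.read_csv(dir_path / "sample_meta.csv", index_col="sample_id")
    adt_path = dir_path / "adt.csv"
    adt = pd.read_csv(adt_path, index_col="marker") if adt_path.exists() else None
    return CellCohort(
        counts=counts,
        gene_ids=gene_ids,
        cell_barcodes=barcodes,
        cell_meta=cell_meta,
        sample_meta=sample_meta,
        adt=adt,
    )
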