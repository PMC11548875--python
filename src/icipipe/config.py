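"""Pipeline configuration.

Every stage parameter lives in a small dataclass whose defaults are the
values the analysis is defined with; anything unstated by the protocol is
documented in docs/methods.md. Configuration round-trips through YAML so a
run is fully described by one file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class QcThresholds:
    """Cell-level quality filters.

    Cells are kept when the mitochondrial UMI fraction is strictly below
    ``mito_fraction_max``, the number of detected genes is strictly above
    ``min_genes_detected``, and the cell is not flagged as a doublet.
    """

    mito_fraction_max: float = 0.20
    min_genes_detected: int = 200
    mito_gene_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not 0 < self.mito_fraction_max <= 1:
            raise ValueError("mito_fraction_max must be in (0, 1]")
        if self.min_genes_detected < 0:
            raise ValueError("min_genes_detected must be >= 0")


@dataclass
class AdtGateParams:
    """ADT-assisted CD4/CD8/NK gate parameters."""

    adt_percentile: float = 55.0
    cd4_marker: str = "CD4"
    cd8_marker: str = "CD8"
    cd3_genes: tuple[str, ...] = ("CD3D", "CD3E", "CD3G")
    nk_marker_genes: tuple[str, ...] = ("XCL1", "NCAM1", "KLRD1", "KLRF1")
    unassigned_prob_threshold: float = 0.55
    n_pcs: int = 30
    min_reference_cells: int = 20
    adt_transform: str = "clr"  # "clr" or "raw"

    def __post_init__(self) -> None:
        if not 0 < self.adt_percentile < 100:
            raise ValueError("adt_percentile must be in (0, 100)")


@dataclass
class CnvParams:
    """Expression-based CNV inference and malignant-call parameters."""

    expression_cutoff: float = 0.1
    window_genes: int = 101
    clip_bound: float = 3.0
    denoise: bool = True
    noise_sd_multiplier: float = 3.0
    exclude_chromosomes: tuple[str, ...] = ("chrM",)
    sd_threshold: float = 0.03
    cor_threshold: float = 0.3
    top_cell_fraction: float = 0.05
    max_reference_epithelial_fraction: float = 0.20
    # recorded for provenance only; the simplified aneuploid caller does not
    # interpret them
    copykat_ngene_chr: int = 3
    copykat_ks_cut: float = 0.05

    def __post_init__(self) -> None:
        if self.window_genes < 3 or self.window_genes % 2 == 0:
            raise ValueError("window_genes must be odd and >= 3")
        if not 0 < self.top_cell_fraction < 1:
            raise ValueError("top_cell_fraction must be in (0, 1)")


@dataclass
class DegThresholds:
    """Four-way differential-expression filter."""

    min_abs_logfc: float = 0.25
    max_p: float = 0.01
    max_adj_p: float = 0.01
    min_pct: float = 0.25

    def __post_init__(self) -> None:
        if self.min_abs_logfc <= 0:
            raise ValueError("min_abs_logfc must be > 0")
        for name in ("max_p", "max_adj_p", "min_pct"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class NmfParams:
    rank: int = 30
    top_genes_per_factor: int = 50
    max_iter: int = 200
    tol: float = 1e-5
    assignment_margin: float = 0.25
    share_normalization: str = "mean"  # "mean" (per-cell mean) or "sum"


@dataclass
class PcaSigParams:
    n_pcs: int = 10
    top_genes: int = 30
    n_hvg: int = 2000


@dataclass
class CloneSizeBins:
    """Clone-size classes as half-open upper bounds (size <= bound)."""

    bounds: tuple[tuple[str, float], ...] = (
        ("Single", 1),
        ("Small", 5),
        ("Medium", 10),
        ("Large", 20),
        ("Hyperexpanded", float("inf")),
    )

    def __post_init__(self) -> None:
        vals = [b for _, b in self.bounds]
        if any(b >= a for b, a in zip(vals, vals[1:])):
            raise ValueError("clone-size bounds must be strictly increasing")


@dataclass
class NormScaleParams:
    scale_factor: float = 1e4
    n_hvg: int = 2000
    clip_bound: float = 10.0
    hvg_loess_span: float = 0.3


@dataclass
class ClassifierParams:
    top_k_features: int = 6
    t_test_variant: str = "welch"  # or "pooled"
    combination_rule: str = "sum"  # or "regression"
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    """Top-level configuration: one block per stage plus seed and paths."""

    seed: int = 0
    outdir: str = "icipipe_out"
    stages: tuple[str, ...] = (
        "simulate",
        "qc",
        "gate",
        "cnv",
        "programs",
        "repertoire",
        "classify",
    )
    qc: QcThresholds = field(default_factory=QcThresholds)
    norm: NormScaleParams = field(default_factory=NormScaleParams)
    gate: AdtGateParams = field(default_factory=AdtGateParams)
    cnv: CnvParams = field(default_factory=CnvParams)
    deg: DegThresholds = field(default_factory=DegThresholds)
    nmf: NmfParams = field(default_factory=NmfParams)
    pca_sig: PcaSigParams = field(default_factory=PcaSigParams)
    clone_bins: CloneSizeBins = field(default_factory=CloneSizeBins)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    sim: dict[str, Any] = field(default_factory=dict)  # SimConfig overrides


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, float) and obj == float("inf"):
        return ".inf"
    return obj


_BLOCKS = {
    "qc": QcThresholds,
    "norm": NormScaleParams,
    "gate": AdtGateParams,
    "cnv": CnvParams,
    "deg": DegThresholds,
    "nmf": NmfParams,
    "pca_sig": PcaSigParams,
    "classifier": ClassifierParams,
}


def config_to_yaml(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def config_from_yaml(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(data)


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _BLOCKS and isinstance(value, dict):
            kwargs[key] = _BLOCKS[key](**{k: _coerce(v) for k, v in value.items()})
        elif key == "clone_bins" and isinstance(value, dict):
            bounds = tuple(
                (name, float("inf") if b in (".inf", "inf", None) else b)
                for name, b in value.get("bounds", [])
            )
            kwargs[key] = CloneSizeBins(bounds=bounds)
        elif key == "stages":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def _coerce(v: Any) -> Any:
    if isinstance(v, list):
        return tuple(v)
    return v
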