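"""Synthetic cohort generator with ground truth for every downstream stage.

The generator emulates a CITE-seq cohort of advanced NSCLC tumor biopsies
from ICI-treated patients: negative-binomial (gamma-Poisson) UMI counts over
lineage-specific marker programs, per-sample cell-type composition drawn
from a Dirichlet whose log-mean shifts with the sample's response group,
malignant epithelial cells carrying arm-level CNV expression shifts and
RECIST-dependent tumor gene programs, ADT counts that separate CD4/CD8/NK,
and clonally expanded paired-chain TCR/BCR repertoires.

Every cell carries truth labels (subtype, malignant flag, clonotype id,
planted QC failures) so recovery by the analysis stages can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import genesets, io
from .cohort import RECIST_TO_RESPONSE, CellCohort, GenePositionTable

# --------------------------------------------------------------------------
# subtype panel

SUBTYPES = (
    "CD4_TN", "CD4_TCM", "CD4_TRM", "CD4_Treg", "CD4_TH17",
    "CD8_TN", "CD8_TEM", "CD8_TEFF", "CD8_TEX",
    "NK", "B", "Myeloid", "Mast", "Epithelial",
)

COMPARTMENT = {
    **{s: "CD4T" for s in SUBTYPES if s.startswith("CD4")},
    **{s: "CD8T" for s in SUBTYPES if s.startswith("CD8")},
    "NK": "NK", "B": "B", "Myeloid": "Myeloid", "Mast": "Mast",
    "Epithelial": "Epithelial",
}

#: coarse cluster-level annotation each subtype would receive
LINEAGE = {
    **{s: "T/NK" for s in SUBTYPES if s.startswith(("CD4", "CD8")) or s == "NK"},
    "B": "B/plasma", "Myeloid": "Myeloid", "Mast": "Mast",
    "Epithelial": "Epithelial",
}

_T_COMMON = ("CD3D", "CD3E", "CD3G", "CD2")
_PANEL = {
    "CD4_TN": _T_COMMON + ("CD4", "IL7R", "CCR7", "SELL", "TCF7", "LEF1"),
    "CD4_TCM": _T_COMMON + ("CD4", "IL7R", "GPR183", "ANXA1"),
    "CD4_TRM": _T_COMMON + ("CD4", "IL7R", "NR4A1", "MYADM", "PTGER4"),
    "CD4_Treg": _T_COMMON + ("CD4",) + genesets.REGULATORY_GENES,
    "CD4_TH17": _T_COMMON + ("CD4", "IL7R", "RORC", "CCR6", "IL23R", "KLRB1"),
    "CD8_TN": _T_COMMON + ("CD8A", "CD8B", "CCR7", "SELL", "TCF7", "LEF1"),
    "CD8_TEM": _T_COMMON + ("CD8A", "CD8B", "GZMK", "GZMA", "GZMH", "KLRG1"),
    "CD8_TEFF": _T_COMMON + ("CD8A", "CD8B", "PRF1", "GZMB", "GNLY", "NKG7", "CX3CR1"),
    "CD8_TEX": _T_COMMON + ("CD8A", "CD8B", "HAVCR2", "PDCD1", "TOX", "CXCL13"),
    "NK": ("XCL1", "NCAM1", "KLRD1", "KLRF1", "FCGR3A"),
    "B": ("CD79A", "MS4A1", "JCHAIN"),
    "Myeloid": ("LYZ", "CD68", "AIF1"),
    "Mast": ("TPSAB1", "CPA3", "KIT"),
    "Epithelial": ("EPCAM", "KRT18", "KRT19", "SFTPC"),
}

#: coarse expression family sharing a dense lineage program
_FAMILY = {
    **{s: "T" for s in SUBTYPES if s.startswith(("CD4", "CD8"))},
    "NK": "NK", "B": "B", "Myeloid": "Myeloid", "Mast": "Mast",
    "Epithelial": "Epithelial",
}

MT_GENES = tuple(
    f"MT-{g}" for g in (
        "ND1", "ND2", "CO1", "CO2", "ATP8", "ATP6", "CO3",
        "ND3", "ND4L", "ND4", "ND5", "ND6", "CYB",
    )
)

_CYCLE_GENES = genesets.S_PHASE_GENES + genesets.G2M_GENES


def _named_genes() -> list[str]:
    seen: dict[str, None] = {}
    for panel in _PANEL.values():
        for g in panel:
            seen.setdefault(g)
    for g in _CYCLE_GENES:
        seen.setdefault(g)
    return list(seen)


_BASE_PROPORTIONS = {
    "Epithelial": 0.18, "B": 0.08, "Myeloid": 0.10, "Mast": 0.02, "NK": 0.06,
    "CD4_TN": 0.06, "CD4_TCM": 0.06, "CD4_TRM": 0.07, "CD4_Treg": 0.08,
    "CD4_TH17": 0.04, "CD8_TN": 0.05, "CD8_TEM": 0.09, "CD8_TEFF": 0.05,
    "CD8_TEX": 0.04,
}


def default_composition_effects() -> dict[str, dict[str, float]]:
    """Planted response-group composition shifts (log-odds)."""
    return {
        "CD4_Treg": {"non-responder": 0.7},
        "CD4_TRM": {"non-responder": 0.7},
        "CD4_TH17": {"non-responder": 0.7},
        "CD8_TEM": {"responder": 0.7},
    }


# --------------------------------------------------------------------------
# configuration


@dataclass
class SimConfig:
    n_samples: int = 14
    samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"PR": 5, "SD": 3, "PD": 6}
    )
    cells_per_sample: int = 600
    n_genes: int = 2000
    nb_dispersion: float = 0.05
    library_log_mean: float = math.log(20000.0)
    library_log_sd: float = 0.15
    marker_multiplier: float = 8.0
    #: marker base weight relative to the median gene; markers are reliably
    #: detected in their lineage without dominating the library
    marker_base_weight: float = 0.15
    background_leak: float = 0.05
    #: dense lineage expression divergence: per-gene lognormal sigma shared
    #: within an expression family, plus a smaller per-subtype component
    family_variation_sd: float = 0.25
    subtype_variation_sd: float = 0.08
    mito_fraction: float = 0.05
    dirichlet_concentration: float = 150.0
    patient_effect_sd: float = 0.10
    base_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_BASE_PROPORTIONS)
    )
    composition_effects: dict[str, dict[str, float]] = field(
        default_factory=default_composition_effects
    )
    #: name -> {"genes": [...], "fold": f, "groups": [RECIST groups]}
    tumor_program_panel: dict[str, dict[str, Any]] | None = None
    #: (chromosome, start index within chromosome, n genes, fold change)
    cnv_events: list[tuple[str, int, int, float]] | None = None
    malignant_fraction: float = 0.85
    adt_separation: dict[str, float] = field(
        default_factory=lambda: {
            "positive_mean": 300.0, "background_mean": 10.0, "dispersion": 0.25
        }
    )
    clonal_expansion: dict[str, float] = field(
        default_factory=lambda: {
            "CD8_TEX": 1.6, "CD8_TEM": 2.2, "CD8_TEFF": 2.2,
            "default": 3.0, "max_clone": 60,
        }
    )
    doublet_rate: float = 0.03
    high_mito_rate: float = 0.02
    low_depth_rate: float = 0.02
    cycling_rate: float = 0.15
    cycling_multiplier: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.samples_per_group.values()) != self.n_samples:
            raise ValueError("samples_per_group must sum to n_samples")
        for name, prog in (self.tumor_program_panel or {}).items():
            if prog["fold"] <= 0:
                raise ValueError(f"program {name}: fold change must be > 0")
        for eff in self.composition_effects.values():
            if any(not np.isfinite(v) for v in eff.values()):
                raise ValueError("composition effects must be finite")
        if self.cnv_events is None:
            self.cnv_events = default_cnv_events(self.n_genes)
        if self.tumor_program_panel is None:
            self.tumor_program_panel = default_tumor_programs(self.n_genes)


def default_cnv_events(n_genes: int) -> list[tuple[str, int, int, float]]:
    """Arm-level gain (300 genes x1.5) and loss (200 genes x0.6).

    Requires the default chromosome layout of >=2000 genes; smaller
    universes get no events.
    """
    if n_genes < 2000:
        return []
    return [("chr1", 50, 300, 1.5), ("chr2", 50, 200, 0.6)]


def default_tumor_programs(n_genes: int) -> dict[str, dict[str, Any]]:
    """RECIST-dependent malignant gene programs on filler genes.

    The shared non-responder program (80 genes x1.6, SD+PD samples) is the
    planted counterpart of the response-discriminating tumor signature;
    per-RECIST programs give the NMF stage group-specific factors.
    """
    if n_genes < 2000:
        return {}
    g = [f"GENE{i:04d}" for i in range(n_genes)]
    return {
        "NR": {"genes": g[1400:1480], "fold": 1.6, "groups": ["SD", "PD"]},
        "PR": {"genes": g[1480:1540], "fold": 1.5, "groups": ["PR"]},
        "SD": {"genes": g[1600:1640], "fold": 1.5, "groups": ["SD"]},
        "PD": {"genes": g[1640:1680], "fold": 1.5, "groups": ["PD"]},
    }


@dataclass
class TruthLabels:
    cells: pd.DataFrame  # subtype, compartment, lineage, malignant, doublet, ...
    gene_programs: dict[str, list[str]]

    def __post_init__(self) -> None:
        bad = self.cells.query("malignant and lineage != 'Epithelial'")
        if len(bad):
            raise ValueError("malignant cells must be epithelial lineage")


# --------------------------------------------------------------------------
# gene universe


@dataclass
class GeneUniverse:
    gene_ids: pd.Index
    positions: GenePositionTable
    named_index: dict[str, int]
    mt_index: np.ndarray


def build_gene_universe(n_genes: int) -> GeneUniverse:
    """Gene ids + genomic layout.

    The last 13 slots are the mitochondrial genes (chrM). The remaining
    autosomal genes split over 8 chromosomes, the first two large enough to
    host arm-level events. Named marker genes are scattered evenly across
    the autosomes (as real lineage markers are), avoiding the default event
    and program regions so planted truth stays clean.
    """
    named = _named_genes()
    n_auto = n_genes - len(MT_GENES)
    if n_auto < len(named) + 50:
        raise ValueError(f"n_genes={n_genes} too small for the marker panel")
    gene_names = [f"GENE{i:04d}" for i in range(n_genes)]

    reserved: set[int] = set()
    if n_genes >= 2000:
        reserved |= set(range(50, 350)) | set(range(450, 650))   # CNV events
        reserved |= set(range(1400, 1680))                        # programs
    candidates = [i for i in range(n_auto) if i not in reserved]
    # fixed permutation so no panel (or the cell-cycle list) clusters on one
    # chromosome; layout is part of the universe, not of a cohort draw
    named = list(np.random.default_rng(190_721).permutation(named))
    pick = np.linspace(0, len(candidates) - 1, len(named)).round().astype(int)
    named_index: dict[str, int] = {}
    for name, ci in zip(named, pick):
        gi = candidates[ci]
        gene_names[gi] = name
        named_index[name] = gi
    mt_index = np.arange(n_auto, n_genes)
    for name, gi in zip(MT_GENES, mt_index):
        gene_names[gi] = name

    sizes = _chromosome_sizes(n_auto)
    rows = []
    start = 0
    for chrom, size in sizes:
        for k in range(size):
            rows.append((gene_names[start + k], chrom, 1 + k * 10_000, 1 + k * 10_000 + 5_000))
        start += size
    for k, name in enumerate(MT_GENES):
        rows.append((name, "chrM", 1 + k * 1_000, 1 + k * 1_000 + 800))
    positions = GenePositionTable(
        pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"]),
        chromosome_order=tuple(c for c, _ in sizes) + ("chrM",),
    )
    return GeneUniverse(pd.Index(gene_names), positions, named_index, mt_index)


def _chromosome_sizes(n_auto: int) -> list[tuple[str, int]]:
    if n_auto >= 1600:
        big = 400
        rest = n_auto - 2 * big
        base = rest // 6
        sizes = [big, big] + [base] * 6
        sizes[-1] += rest - 6 * base
    else:
        base = n_auto // 4
        sizes = [base] * 4
        sizes[-1] += n_auto - 4 * base
    return [(f"chr{i + 1}", s) for i, s in enumerate(sizes)]


# --------------------------------------------------------------------------
# expected means


def plant_cnv_events(
    base_means: pd.DataFrame,
    events: list[tuple[str, int, int, float]],
    positions: GenePositionTable,
    malignant_rows: list[str] | None = None,
) -> pd.DataFrame:
    """Multiply event genes' expected means for malignant lineages only.

    ``base_means`` is lineage x gene. Events reference contiguous gene runs
    within one chromosome ((chrom, start offset, n genes, fold)); events
    overlapping on any gene are an error.
    """
    malignant_rows = malignant_rows if malignant_rows is not None else ["Malignant"]
    out = base_means.copy()
    mult = cnv_multiplier(events, positions, pd.Index(base_means.columns))
    for row in malignant_rows:
        out.loc[row] = out.loc[row] * mult
    return out


def cnv_multiplier(
    events: list[tuple[str, int, int, float]],
    positions: GenePositionTable,
    gene_ids: pd.Index,
) -> np.ndarray:
    """Per-gene fold-change vector implied by the event list."""
    mult = np.ones(len(gene_ids))
    touched = np.zeros(len(gene_ids), dtype=bool)
    tab = positions.table
    for chrom, start, n, fold in events:
        if fold <= 0:
            raise ValueError("fold change must be > 0")
        chrom_genes = tab.loc[tab["chromosome"] == chrom].sort_values("start")["gene_id"]
        if start + n > len(chrom_genes):
            raise ValueError(
                f"event on {chrom} runs past the chromosome "
                f"({start}+{n} > {len(chrom_genes)} genes)"
            )
        idx = gene_ids.get_indexer(chrom_genes.iloc[start : start + n])
        idx = idx[idx >= 0]
        if touched[idx].any():
            raise ValueError(f"overlapping CNV events on {chrom}")
        touched[idx] = True
        mult[idx] *= fold
    return mult


def event_gene_ids(
    events: list[tuple[str, int, int, float]], positions: GenePositionTable
) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    tab = positions.table
    for chrom, start, n, fold in events:
        genes = (
            tab.loc[tab["chromosome"] == chrom].sort_values("start")["gene_id"]
            .iloc[start : start + n].tolist()
        )
        out[f"cnv_{chrom}_x{fold}"] = genes
    return out


def _lineage_profiles(cfg: SimConfig, uni: GeneUniverse, rng: np.random.Generator) -> pd.DataFrame:
    """Subtype x gene expected relative expression, rows summing to 1."""
    n = cfg.n_genes
    w = rng.lognormal(0.0, 1.2, n)
    cycle = {g for g in _CYCLE_GENES}
    for name, gi in uni.named_index.items():
        w[gi] = 1.0 if name in cycle else cfg.marker_base_weight
    M = np.ones((len(SUBTYPES), n))
    targets: dict[int, set[int]] = {}
    for si, sub in enumerate(SUBTYPES):
        for g in _PANEL[sub]:
            targets.setdefault(uni.named_index[g], set()).add(si)
    for gi, subs in targets.items():
        M[:, gi] = cfg.background_leak
        for si in subs:
            M[si, gi] = cfg.marker_multiplier
    # dense lineage divergence: many genes, moderate fold changes (the
    # realistic regime for expression-based CNV references), shared within
    # an expression family plus a small subtype-private component
    families = sorted(set(_FAMILY.values()))
    fam_factor = {
        f: np.exp(rng.normal(0.0, cfg.family_variation_sd, n)) for f in families
    }
    dense = np.vstack(
        [
            fam_factor[_FAMILY[sub]]
            * np.exp(rng.normal(0.0, cfg.subtype_variation_sd, n))
            for sub in SUBTYPES
        ]
    )
    prof = M * dense * w[None, :]
    # pin the mitochondrial fraction, then normalize rows
    mt = uni.mt_index
    auto_mass = np.delete(prof, mt, axis=1).sum(axis=1)
    prof[:, mt] = (cfg.mito_fraction / (1 - cfg.mito_fraction)) * (
        auto_mass[:, None] / len(mt)
    )
    prof /= prof.sum(axis=1, keepdims=True)
    return pd.DataFrame(prof, index=list(SUBTYPES), columns=uni.gene_ids)


# --------------------------------------------------------------------------
# repertoire


_TRAV = [f"TRAV{i}" for i in range(1, 9)]
_TRAJ = [f"TRAJ{i}" for i in range(1, 9)]
_TRBV = [f"TRBV{i}" for i in range(1, 9)]
_TRBD = ["TRBD1", "TRBD2"]
_TRBJ = [f"TRBJ{i}" for i in range(1, 9)]
_TRBC = ["TRBC1", "TRBC2"]
_IGHV = [f"IGHV{i}" for i in range(1, 9)]
_IGHD = [f"IGHD{i}" for i in range(1, 4)]
_IGHJ = [f"IGHJ{i}" for i in range(1, 7)]
_IGHC = ["IGHM", "IGHG1"]
_IGLIGHT = {
    "IGK": ([f"IGKV{i}" for i in range(1, 7)], [f"IGKJ{i}" for i in range(1, 6)], ["IGKC"]),
    "IGL": ([f"IGLV{i}" for i in range(1, 7)], [f"IGLJ{i}" for i in range(1, 4)], ["IGLC1"]),
}


def _cdr3(rng: np.random.Generator) -> str:
    length = int(rng.integers(30, 46))
    return "".join(rng.choice(list("ACGT"), length))


def _clone_sizes(m: int, gamma: float, max_clone: int, rng: np.random.Generator) -> list[int]:
    s = np.arange(1, max_clone + 1)
    p = s.astype(float) ** -gamma
    p /= p.sum()
    sizes: list[int] = []
    left = m
    while left > 0:
        size = min(int(rng.choice(s, p=p)), left)
        sizes.append(size)
        left -= size
    return sizes


def simulate_repertoire(
    cell_truth: pd.DataFrame,
    clonal_expansion: dict[str, float],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.Series]:
    """Paired-chain contigs for T (TRA+TRB) and B (IGH + IGK/IGL) cells.

    Cells sharing a clonotype share V(D)JC genes and CDR3 nucleotide
    sequences on both chains. Clone sizes follow a truncated power law per
    (sample, subtype), with a heavier tail for exhausted CD8 T cells.
    Returns the contig table and the per-cell truth clonotype id.
    """
    max_clone = int(clonal_expansion.get("max_clone", 60))
    default_gamma = clonal_expansion.get("default", 3.0)
    rows: list[tuple] = []
    clono = pd.Series(pd.NA, index=cell_truth.index, dtype="object")
    counter = 0
    receptor_cells = cell_truth[
        cell_truth["compartment"].isin(["CD4T", "CD8T", "B"]) & ~cell_truth["doublet"]
    ]
    for (sample, subtype), grp in receptor_cells.groupby(
        ["sample_id", "subtype"], sort=True
    ):
        gamma = clonal_expansion.get(subtype, default_gamma)
        barcodes = grp.index.to_numpy()
        rng.shuffle(barcodes)
        pos = 0
        for size in _clone_sizes(len(barcodes), gamma, max_clone, rng):
            counter += 1
            cid = f"truthcl{counter:05d}"
            members = barcodes[pos : pos + size]
            pos += size
            clono.loc[members] = cid
            if COMPARTMENT[subtype] == "B":
                heavy = ("IGH", rng.choice(_IGHV), rng.choice(_IGHD),
                         rng.choice(_IGHJ), rng.choice(_IGHC), _cdr3(rng))
                lk = rng.choice(list(_IGLIGHT))
                vs, js, cs = _IGLIGHT[lk]
                light = (lk, rng.choice(vs), "", rng.choice(js), rng.choice(cs), _cdr3(rng))
                chains = (heavy, light)
            else:
                alpha = ("TRA", rng.choice(_TRAV), "", rng.choice(_TRAJ), "TRAC", _cdr3(rng))
                beta = ("TRB", rng.choice(_TRBV), rng.choice(_TRBD),
                        rng.choice(_TRBJ), rng.choice(_TRBC), _cdr3(rng))
                chains = (alpha, beta)
            for bc in members:
                for chain, v, d, j, c, nt in chains:
                    rows.append((bc, chain, v, d, j, c, nt, int(rng.integers(2, 20))))
    contigs = pd.DataFrame(
        rows, columns=io.CONTIG_COLUMNS + ["umis"]
    )
    return contigs, clono


# --------------------------------------------------------------------------
# main generator


def simulate_cohort(cfg: SimConfig) -> tuple[CellCohort, TruthLabels, pd.DataFrame]:
    """Draw one cohort -> (CellCohort, TruthLabels, contig table)."""
    rng = np.random.default_rng(cfg.seed)
    uni = build_gene_universe(cfg.n_genes)
    profiles = _lineage_profiles(cfg, uni, rng)
    cnv_mult = cnv_multiplier(cfg.cnv_events, uni.positions, uni.gene_ids)

    prog_mult = {g: np.ones(cfg.n_genes) for g in ("PR", "SD", "PD")}
    gene_programs: dict[str, list[str]] = {}
    for name, prog in cfg.tumor_program_panel.items():
        idx = uni.gene_ids.get_indexer(prog["genes"])
        if (idx < 0).any():
            raise ValueError(f"program {name} references unknown genes")
        gene_programs[f"program_{name}"] = list(prog["genes"])
        for grp in prog["groups"]:
            prog_mult[grp][idx] *= prog["fold"]
    gene_programs.update(event_gene_ids(cfg.cnv_events, uni.positions))

    sample_meta = _sample_meta(cfg, rng)
    sub_idx = {s: i for i, s in enumerate(SUBTYPES)}
    base_p = np.array([cfg.base_proportions[s] for s in SUBTYPES])
    base_p = base_p / base_p.sum()

    cycle_idx = uni.gene_ids.get_indexer(
        [g for g in _CYCLE_GENES if g in uni.gene_ids]
    )
    count_blocks, adt_blocks, meta_rows = [], [], []
    for sample_id, srow in sample_meta.iterrows():
        shift = np.array(
            [
                cfg.composition_effects.get(s, {}).get(srow["response"], 0.0)
                for s in SUBTYPES
            ]
        )
        p = base_p * np.exp(shift)
        p /= p.sum()
        props = rng.dirichlet(cfg.dirichlet_concentration * p)
        n_by_type = rng.multinomial(cfg.cells_per_sample, props)
        subtypes = np.repeat(np.arange(len(SUBTYPES)), n_by_type)
        rng.shuffle(subtypes)
        n = len(subtypes)

        lib = rng.lognormal(cfg.library_log_mean, cfg.library_log_sd, n)
        low_depth = rng.random(n) < cfg.low_depth_rate
        lib[low_depth] *= 0.006
        high_mito = rng.random(n) < cfg.high_mito_rate
        cycling = rng.random(n) < cfg.cycling_rate
        # malignancy in this model is aneuploidy: without planted CNV events
        # every epithelial cell is diploid and no cell is malignant
        mal_frac = cfg.malignant_fraction if cfg.cnv_events else 0.0
        malignant = (np.array(SUBTYPES)[subtypes] == "Epithelial") & (
            rng.random(n) < mal_frac
        )
        patient_factor = np.exp(rng.normal(0.0, cfg.patient_effect_sd, cfg.n_genes))

        mu = profiles.to_numpy()[subtypes] * patient_factor[None, :]  # cells x genes
        mu[malignant] *= (cnv_mult * prog_mult[srow["recist"]])[None, :]
        if cycling.any() and len(cycle_idx):
            mu[np.ix_(cycling, cycle_idx)] *= cfg.cycling_multiplier
        if high_mito.any():
            mu[np.ix_(high_mito, uni.mt_index)] *= 8.0
        mu *= lib[:, None] / 1.0
        shape = 1.0 / cfg.nb_dispersion
        counts = rng.poisson(rng.gamma(shape, mu * cfg.nb_dispersion)).astype(np.int32)
        count_blocks.append(counts)

        adt_blocks.append(_draw_adt(cfg, np.array(SUBTYPES)[subtypes], rng))
        for i in range(n):
            sub = SUBTYPES[subtypes[i]]
            meta_rows.append(
                (
                    f"{sample_id}_C{i:04d}", sample_id, srow["patient_id"], sub,
                    COMPARTMENT[sub], LINEAGE[sub], bool(malignant[i]),
                    bool(low_depth[i] or high_mito[i]), bool(cycling[i]),
                    float(lib[i]),
                )
            )

    counts = np.vstack(count_blocks).T  # genes x cells
    adt = np.hstack(adt_blocks)
    truth_cells = pd.DataFrame(
        meta_rows,
        columns=[
            "barcode", "sample_id", "patient_id", "subtype", "compartment",
            "lineage", "malignant", "qc_fail", "cycling", "library_size",
        ],
    ).set_index("barcode")
    truth_cells["doublet"] = False

    # doublets: within-sample pairs, the first member becomes the sum
    n_cells = counts.shape[1]
    barcode_pos = {b: i for i, b in enumerate(truth_cells.index)}
    for sample_id in sample_meta.index:
        cells = truth_cells.index[truth_cells["sample_id"] == sample_id].to_numpy()
        k = int(round(cfg.doublet_rate * len(cells)))
        if k == 0:
            continue
        chosen = rng.choice(cells, size=2 * k, replace=False)
        for a, b in zip(chosen[:k], chosen[k:]):
            ia, ib = barcode_pos[a], barcode_pos[b]
            counts[:, ia] += counts[:, ib]
            adt[:, ia] += adt[:, ib]
            truth_cells.loc[a, "doublet"] = True

    contigs, clono = simulate_repertoire(truth_cells, cfg.clonal_expansion, rng)
    truth_cells["clonotype_id"] = clono

    cell_meta = truth_cells[
        ["sample_id", "patient_id", "lineage", "subtype", "compartment", "doublet"]
    ].copy()
    cell_meta["truth_malignant"] = truth_cells["malignant"]
    cohort = CellCohort(
        counts=counts,
        gene_ids=uni.gene_ids,
        cell_barcodes=truth_cells.index,
        cell_meta=cell_meta,
        sample_meta=sample_meta,
        adt=pd.DataFrame(adt, index=list(ADT_MARKERS), columns=truth_cells.index),
    )
    truth = TruthLabels(cells=truth_cells, gene_programs=gene_programs)
    cohort.positions = uni.positions  # genomic layout travels with the cohort
    cohort.contigs = contigs
    return cohort, truth, contigs


def _sample_meta(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    k = 0
    for recist, count in cfg.samples_per_group.items():
        for _ in range(count):
            k += 1
            rows.append(
                (
                    f"S{k:02d}", f"P{k:02d}", recist, RECIST_TO_RESPONSE[recist],
                    rng.choice(["lung", "LN", "pleura"], p=[0.6, 0.3, 0.1]),
                    rng.choice(["LUAD", "LUSC"], p=[0.7, 0.3]),
                    rng.choice(["III", "IV"], p=[0.4, 0.6]),
                    rng.choice(["ever", "never"], p=[0.6, 0.4]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "patient_id", "recist", "response",
            "tissue_origin", "subtype", "stage", "smoking",
        ],
    ).set_index("sample_id")


ADT_MARKERS = ("CD3", "CD4", "CD8", "CD56", "CD19", "CD14", "CD45")

#: subtypes in which each ADT marker reads positive
_ADT_POSITIVE = {
    "CD3": tuple(s for s in SUBTYPES if s.startswith(("CD4", "CD8"))),
    "CD4": tuple(s for s in SUBTYPES if s.startswith("CD4")) + ("Myeloid",),
    "CD8": tuple(s for s in SUBTYPES if s.startswith("CD8")),
    "CD56": ("NK",),
    "CD19": ("B",),
    "CD14": ("Myeloid",),
    "CD45": tuple(s for s in SUBTYPES if s != "Epithelial"),
}


def _draw_adt(cfg: SimConfig, subtypes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    sep = cfg.adt_separation
    pos, bg, disp = sep["positive_mean"], sep["background_mean"], sep["dispersion"]
    mu = np.full((len(ADT_MARKERS), len(subtypes)), bg)
    for i, marker in enumerate(ADT_MARKERS):
        mu[i, np.isin(subtypes, _ADT_POSITIVE[marker])] = pos
        if marker == "CD4":  # monocytes are dim-positive for CD4
            mu[i, subtypes == "Myeloid"] = 0.2 * pos
    shape = 1.0 / disp
    return rng.poisson(rng.gamma(shape, mu * disp)).astype(np.int32)


# --------------------------------------------------------------------------
# writing


def write_simulated(
    dir_path: str | Path,
    cohort: CellCohort,
    truth: TruthLabels,
    contigs: pd.DataFrame,
    cfg: SimConfig,
) -> None:
    """Emit the exact on-disk dialect the readers consume, plus truth."""
    dir_path = Path(dir_path)
    io.write_cohort(dir_path, cohort)
    io.write_vdj_contigs(dir_path / "contigs.csv", contigs)
    io.write_gene_positions(dir_path / "gene_positions.tsv", cohort.positions)
    truth.cells.to_csv(dir_path / "truth_labels.csv", index_label="barcode")
    plain = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in cfg.__dict__.items()
    }
    plain["cnv_events"] = [list(e) for e in cfg.cnv_events]
    (dir_path / "sim_config.yaml").write_text(yaml.safe_dump(plain, sort_keys=False))
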