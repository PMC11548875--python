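"""Stage-oriented pipeline: simulate -> qc -> gate -> cnv -> programs ->
repertoire -> classify.

Each stage consumes and extends a shared context dict; ``run_pipeline``
executes the configured stage list in order, writes every intermediate
table as CSV (matrices as Matrix Market) and logs the parameters actually
applied. Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import classify as cls
from . import cnv as cnv_mod
from . import gating, genesets, programs, qc, repertoire, simulate
from .config import PipelineConfig, config_to_yaml

log = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "qc", "gate", "cnv", "programs", "repertoire", "classify")

IMMUNE_SUBTYPES = tuple(s for s in simulate.SUBTYPES if s != "Epithelial")


def _cc_covariates(norm: qc.NormalizedMatrix) -> np.ndarray | None:
    """Cell-cycle S/G2M scores as regression covariates (None if the gene
    lists are absent from the matrix)."""
    cols = []
    for gene_set in (genesets.S_PHASE_GENES, genesets.G2M_GENES):
        present = [g for g in gene_set if g in norm.gene_ids]
        if present:
            cols.append(qc.score_gene_set(norm, present))
    return np.column_stack(cols) if cols else None


# --------------------------------------------------------------------------
# stages


def stage_simulate(ctx: dict, config: PipelineConfig) -> dict:
    sim_cfg = simulate.SimConfig(**{**config.sim, "seed": config.seed})
    cohort, truth, contigs = simulate.simulate_cohort(sim_cfg)
    ctx.update(
        sim_config=sim_cfg, cohort=cohort, truth=truth, contigs=contigs,
        positions=cohort.positions,
    )
    return ctx


def stage_qc(ctx: dict, config: PipelineConfig) -> dict:
    cohort = ctx["cohort"]
    metrics = qc.qc_metrics(cohort, config.qc)
    keep = qc.qc_filter(cohort, config.qc)
    metrics["keep"] = keep
    filtered = cohort.subset_cells(keep)
    norm = qc.normalize_cohort(filtered, config.norm)
    hvg = qc.select_hvg(
        filtered.counts, filtered.gene_ids,
        n=min(config.norm.n_hvg, filtered.n_genes), span=config.norm.hvg_loess_span,
    )
    ctx.update(qc_report=metrics, filtered=filtered, norm=norm, hvg=hvg)
    if "truth" in ctx:
        ctx["truth_filtered"] = ctx["truth"].cells.loc[filtered.cell_barcodes]
    return ctx


def stage_gate(ctx: dict, config: PipelineConfig) -> dict:
    filtered, norm = ctx["filtered"], ctx["norm"]
    tnk_mask = (filtered.cell_meta["lineage"] == "T/NK").to_numpy()
    sub = filtered.subset_cells(tnk_mask)
    norm_sub = qc.NormalizedMatrix(
        norm.values[:, tnk_mask], norm.gene_ids, sub.cell_barcodes, norm.scale_factor
    )
    scaled = qc.scale_and_regress(
        norm_sub, _cc_covariates(norm_sub), config.norm.clip_bound
    )
    labels = gating.assign_tnk(
        sub.counts, norm_sub, scaled, sub.adt, config.gate, seed=config.seed
    )
    full = pd.DataFrame(
        {"label": pd.NA, "source": pd.NA, "probability": np.nan},
        index=filtered.cell_barcodes,
    )
    full.loc[labels.table.index, ["label", "source", "probability"]] = labels.table
    ctx.update(tnk_labels=full, tnk_result=labels)
    return ctx


def stage_cnv(ctx: dict, config: PipelineConfig) -> dict:
    filtered, norm = ctx["filtered"], ctx["norm"]
    profile = cnv_mod.run_cnv_stage(
        norm, filtered.counts, filtered.cell_meta["lineage"], ctx["positions"],
        config.cnv, seed=config.seed,
    )
    ctx.update(cnv_profile=profile, malignant_mask=profile.calls["consensus_call"].to_numpy())
    return ctx


def stage_programs(ctx: dict, config: PipelineConfig) -> dict:
    filtered, norm = ctx["filtered"], ctx["norm"]
    mal = np.asarray(ctx["malignant_mask"], dtype=bool)
    if mal.sum() < 50:
        raise ValueError(f"only {int(mal.sum())} malignant cells; too few for signatures")
    idx = np.flatnonzero(mal)
    norm_mal = qc.NormalizedMatrix(
        norm.values[:, idx], norm.gene_ids, filtered.cell_barcodes[idx], norm.scale_factor
    )
    counts_mal = filtered.counts[:, idx]
    recist = filtered.cell_meta["sample_id"].map(
        filtered.sample_meta["recist"]
    ).to_numpy()
    response = filtered.cell_meta["sample_id"].map(
        filtered.sample_meta["response"]
    ).to_numpy()

    comparisons = {
        "responder_vs_nonresponder": (
            np.flatnonzero(mal & (response == "responder")),
            np.flatnonzero(mal & (response == "non-responder")),
        ),
        "PR_vs_PD": (
            np.flatnonzero(mal & (recist == "PR")), np.flatnonzero(mal & (recist == "PD"))
        ),
        "PR_vs_SD": (
            np.flatnonzero(mal & (recist == "PR")), np.flatnonzero(mal & (recist == "SD"))
        ),
    }
    deg_tables = {}
    for name, (a, b) in comparisons.items():
        deg_tables[name] = programs.wilcoxon_deg(norm, filtered.counts, a, b, config.deg)
    signatures = programs.build_int_union(list(deg_tables.values()))

    model = programs.fit_nmf(
        counts_mal, config.nmf, norm.gene_ids, norm_mal.cell_barcodes, seed=config.seed
    )
    shares, nmf_sigs = programs.derive_nmf_programs(model, recist[idx], config.nmf)
    signatures.update(nmf_sigs)

    coef_tables, module_groups = {}, {}
    for fac, grp in shares["assigned_group"].items():
        if grp:
            f = int(fac.replace("factor", "")) - 1
            coef_tables[fac] = pd.Series(model.W[:, f], index=model.gene_ids)
            module_groups[fac] = grp
    if coef_tables:
        signatures.update(
            programs.refine_top_gene_modules(coef_tables, module_groups, top_n=100)
        )

    enrichment = None
    if len(nmf_sigs) >= 2:
        assignment = programs.assign_cells_to_programs(norm_mal, nmf_sigs)
        enrichment = programs.enrichment_odds_ratio(assignment, recist[idx])

    hvg_mal = qc.select_hvg(
        counts_mal, norm.gene_ids, n=min(config.pca_sig.n_hvg, len(norm.gene_ids)),
        span=config.norm.hvg_loess_span,
    )
    g_idx = norm.gene_ids.get_indexer(hvg_mal)
    norm_hvg = qc.NormalizedMatrix(
        norm_mal.values[g_idx], pd.Index(hvg_mal), norm_mal.cell_barcodes, norm.scale_factor
    )
    scaled_mal = qc.scale_and_regress(
        norm_hvg, _cc_covariates(norm_hvg), config.norm.clip_bound
    )
    pc_sigs, _ = programs.pca_signatures(scaled_mal, config.pca_sig)
    signatures.update(pc_sigs)

    scores = pd.DataFrame(
        {
            name: programs.score_signature_per_sample(
                norm, sig, mal, filtered.cell_meta["sample_id"]
            )
            for name, sig in signatures.items()
        }
    )
    ctx.update(
        deg_tables=deg_tables, signatures=signatures, nmf_model=model,
        nmf_shares=shares, enrichment=enrichment, signature_scores=scores,
    )
    return ctx


def stage_repertoire(ctx: dict, config: PipelineConfig) -> dict:
    filtered = ctx["filtered"]
    contigs = ctx["contigs"]
    kept = contigs[contigs["barcode"].isin(filtered.cell_barcodes)]
    meta = filtered.cell_meta[["sample_id", "compartment"]]
    blocks = []
    for receptor in ("TCR", "BCR"):
        called = repertoire.call_clonotypes(kept, receptor)
        if not len(called):
            continue
        called = repertoire.classify_clone_sizes(
            called, config.clone_bins,
            compartment=meta["compartment"], sample_id=meta["sample_id"],
        )
        called["receptor"] = receptor
        blocks.append(called)
    clonotypes = pd.concat(blocks) if blocks else pd.DataFrame()
    tmask = filtered.cell_meta["compartment"].isin(["CD4T", "CD8T"]).to_numpy()
    norm = ctx["norm"]
    norm_t = qc.NormalizedMatrix(
        norm.values[:, tmask], norm.gene_ids,
        filtered.cell_barcodes[tmask], norm.scale_factor,
    )
    ctx.update(
        clonotypes=clonotypes, functional_scores=repertoire.functional_scores(norm_t)
    )
    return ctx


def stage_classify(ctx: dict, config: PipelineConfig) -> dict:
    filtered = ctx["filtered"]
    meta = filtered.cell_meta
    immune = meta[meta["lineage"] != "Epithelial"]
    counts_table = pd.crosstab(immune["subtype"], immune["sample_id"])
    counts_table = counts_table.reindex(
        index=[s for s in IMMUNE_SUBTYPES if s in counts_table.index],
        columns=sorted(filtered.sample_meta.index),
        fill_value=0,
    )
    roe = cls.compute_roe(counts_table)

    sample_meta = filtered.sample_meta.loc[roe.columns]
    responders = list(sample_meta.index[sample_meta["response"] == "responder"])
    non_resp = list(sample_meta.index[sample_meta["response"] == "non-responder"])
    comp_rows = []
    props_all = counts_table / counts_table.sum(axis=0)
    t_table = counts_table.loc[
        [s for s in counts_table.index if s.startswith(("CD4", "CD8"))]
    ]
    props_t = t_table / t_table.sum(axis=0)
    for denom, props in (("all_immune", props_all), ("cd4_cd8", props_t)):
        for ct in props.index:
            diff, p = cls.compare_proportions(
                props.loc[ct], responders, non_resp, config.classifier.t_test_variant
            )
            comp_rows.append((ct, denom, diff, p))
    composition = pd.DataFrame(
        comp_rows, columns=["cell_type", "denominator", "mean_diff", "p"]
    )

    features = roe.T.rename(columns=lambda c: f"Roe.{c}")
    if "signature_scores" in ctx:
        features = features.join(ctx["signature_scores"])
    features = features / features.max()  # max-normalize each feature
    response01 = (sample_meta["response"] == "responder").astype(int)

    uni_rows = []
    for f in features.columns:
        coef, p = cls.univariate_regression(features[f], response01)
        uni_rows.append((f, "feature", coef, p))
    for clin in ("tissue_origin", "subtype", "stage", "smoking"):
        coef, p = cls.univariate_regression(sample_meta[clin], response01)
        uni_rows.append((clin, "clinical", coef, p))
    univariate = pd.DataFrame(uni_rows, columns=["name", "kind", "coefficient", "p"])

    screen = cls.screen_combinations(
        features, response01, top_k=config.classifier.top_k_features
    )
    report = _report_md(screen, roe, sample_meta)
    ctx.update(
        roe=roe, composition_tests=composition, feature_matrix=features,
        univariate=univariate, roc_screen=screen, classifier_report=report,
    )
    return ctx


def _report_md(screen: pd.DataFrame, roe: pd.DataFrame, sample_meta: pd.DataFrame) -> str:
    lines = [
        "# Response classification report",
        "",
        f"Samples: {len(sample_meta)} "
        f"({(sample_meta['response'] == 'responder').sum()} responders / "
        f"{(sample_meta['response'] == 'non-responder').sum()} non-responders)",
        "",
        "Top combinatorial indices by in-sample ROC AUC "
        "(p: two-tailed Wilcoxon rank-sum; q: Benjamini-Hochberg):",
        "",
        screen.head(10).to_markdown(index=False, floatfmt=".4f"),
        "",
    ]
    if len(screen):
        best = screen.iloc[0]
        lines.append(
            f"Best index: **{best['name']}** (AUC {best['auc']:.3f}, q {best['q']:.3g})"
        )
    return "\n".join(lines)


# --------------------------------------------------------------------------
# runner


STAGES: dict[str, Callable[[dict, PipelineConfig], dict]] = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "gate": stage_gate,
    "cnv": stage_cnv,
    "programs": stage_programs,
    "repertoire": stage_repertoire,
    "classify": stage_classify,
}

_REQUIRES = {
    "qc": ("cohort",),
    "gate": ("filtered",),
    "cnv": ("filtered",),
    "programs": ("malignant_mask",),
    "repertoire": ("filtered",),
    "classify": ("filtered",),
}


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None, write: bool = True
) -> dict[str, Any]:
    """Execute the configured stages in order; returns the result context.

    Any stage failure aborts with the stage name and cause. With ``write``
    (default) every stage's tables land under ``outdir``.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        config_to_yaml(config, outdir / "config.yaml")
    log.info("pipeline start: seed=%d stages=%s", config.seed, list(config.stages))
    ctx: dict[str, Any] = {}
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        for req in _REQUIRES.get(stage, ()):
            if req not in ctx:
                raise RuntimeError(
                    f"stage '{stage}' requires earlier stage output '{req}'"
                )
        try:
            ctx = STAGES[stage](ctx, config)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
        if write:
            _write_stage(stage, ctx, outdir)
    return ctx


def _write_stage(stage: str, ctx: dict, outdir: Path) -> None:
    if stage == "simulate":
        simulate.write_simulated(
            outdir / "cohort", ctx["cohort"], ctx["truth"], ctx["contigs"],
            ctx["sim_config"],
        )
    elif stage == "qc":
        ctx["qc_report"].to_csv(outdir / "qc_report.csv", index_label="barcode")
        (outdir / "hvg.txt").write_text("".join(f"{g}\n" for g in ctx["hvg"]))
    elif stage == "gate":
        ctx["tnk_labels"].to_csv(outdir / "tnk_labels.csv", index_label="barcode")
    elif stage == "cnv":
        profile = ctx["cnv_profile"]
        pd.concat([profile.summary, profile.calls], axis=1).to_csv(
            outdir / "cnv_summary.csv", index_label="barcode"
        )
        scipy.io.mmwrite(outdir / "cnv_signal.mtx", sp.coo_matrix(profile.signal))
    elif stage == "programs":
        for name, table in ctx["deg_tables"].items():
            table.to_csv(outdir / f"deg_{name}.csv")
        sigs = {
            name: {"genes": list(s.genes), "direction": s.direction,
                   "provenance": s.provenance}
            for name, s in ctx["signatures"].items()
        }
        (outdir / "signatures.json").write_text(json.dumps(sigs, indent=1))
        model = ctx["nmf_model"]
        pd.DataFrame(model.W, index=model.gene_ids).to_csv(outdir / "nmf_W.csv")
        pd.DataFrame(model.H, columns=model.cell_barcodes).to_csv(outdir / "nmf_H.csv")
        ctx["nmf_shares"].to_csv(outdir / "program_shares.csv", index_label="factor")
        if ctx["enrichment"] is not None:
            ctx["enrichment"].to_csv(outdir / "enrichment.csv", index=False)
        ctx["signature_scores"].to_csv(
            outdir / "sample_signature_scores.csv", index_label="sample_id"
        )
    elif stage == "repertoire":
        ctx["clonotypes"].to_csv(outdir / "clonotypes.csv", index_label="barcode")
        ctx["functional_scores"].to_csv(
            outdir / "functional_scores.csv", index_label="barcode"
        )
    elif stage == "classify":
        ctx["roe"].to_csv(outdir / "roe_table.csv", index_label="cell_type")
        ctx["composition_tests"].to_csv(outdir / "composition_tests.csv", index=False)
        ctx["univariate"].to_csv(outdir / "univariate.csv", index=False)
        ctx["roc_screen"].to_csv(outdir / "roc_screen.csv", index=False)
        (outdir / "classifier_report.md").write_text(ctx["classifier_report"])
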