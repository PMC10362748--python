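"""End-to-end orchestration: preprocess -> collapse -> stability -> sPLS ->
screens -> enrichment, plus the PCA overview and report tables.

The stage order mirrors the analysis narrative: LC-MS housekeeping first
(blank/QC filters, weight normalization, satellite collapsing and
peptide flagging on the metabolome), then dual-CV stable-feature
selection per block, then covariation mapping of the stable metabolites
against each omics block, category enrichment of the resulting groups,
and finally the per-metabolite correlation screens.  Each stage is
individually skippable, and the run manifest logs every parameter for
provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import __version__
from .association import ScreenParams, pathway_correlations, screen_metabolite
from .core_model import FeatureMetaMap, OmicsBlock, PathwayMap, StudyDesign, align_blocks
from .enrichment import EnrichmentParams, fisher_enrichment
from .ms_redundancy import (
    DEFAULT_RULES,
    CollapseReport,
    RedundancyParams,
    collapse_block,
    flag_peptides,
)
from .preprocess import PreprocessParams, blank_filter, qc_cv_filter, weight_normalize
from .sparse_pls import SplsModel, SplsParams, fit_spls, group_by_loading, select_covarying
from .stability import StabilityParams, StabilityResult, compute_stability, stability_table

logger = logging.getLogger(__name__)


def overview_pca(block: OmicsBlock) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a block after mean-centring and unit-variance scaling.

    Samples are observations.  Features with missing values or zero
    variance are dropped with a notice.  Returns (scores, loadings,
    variance_explained_percent); the variance fractions sum to 100%.
    """
    data = block.data
    usable = data.notna().all(axis=1) & (data.std(axis=1, ddof=1) > 0)
    dropped = int((~usable).sum())
    if dropped:
        logger.info("overview PCA dropped %d constant/incomplete features", dropped)
    data = data.loc[usable]
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("PCA needs >=2 samples and >=2 non-constant features")
    X = data.T.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    pca = PCA(n_components=min(X.shape) - 1, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = [f"PC{i + 1}" for i in range(scores.shape[1])]
    var_pct = 100.0 * pca.explained_variance_ratio_ / pca.explained_variance_ratio_.sum()
    return (
        pd.DataFrame(scores, index=data.columns, columns=comps),
        pd.DataFrame(pca.components_.T, index=data.index, columns=comps),
        var_pct,
    )


@dataclass
class PipelineConfig:
    """All stage parameters plus per-block stability thresholds."""

    stability: dict = field(
        default_factory=lambda: {
            "metabolome": StabilityParams(25.0, 25.0),
            "proteome": StabilityParams(25.0, 25.0),
            "transcriptome": StabilityParams(40.0, 40.0),
        }
    )
    preprocess: PreprocessParams | None = None
    redundancy: RedundancyParams = field(default_factory=RedundancyParams)
    spls: SplsParams = field(default_factory=SplsParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    loading_threshold: float = 0.6
    run_preprocess: bool = True
    run_collapse: bool = True
    run_spls: bool = True
    run_screens: bool = True
    run_enrichment: bool = True


@dataclass
class PipelineResult:
    config: PipelineConfig
    pca_scores: pd.DataFrame
    pca_variance_pct: np.ndarray
    collapse: CollapseReport | None
    peptide_flags: set
    stability: dict  # block name -> StabilityResult
    stable_metabolites: list
    spls_models: dict  # block name -> SplsModel
    covariation_groups: dict  # block name -> list[CovariationGroup]
    group_enrichment: dict  # (block, group label) -> DataFrame
    screen_summary: pd.DataFrame | None
    screen_records: pd.DataFrame | None
    pathway_tables: pd.DataFrame | None
    provenance: dict


def _params_dict(obj) -> dict:
    if obj is None:
        return {}
    d = dataclasses.asdict(obj)
    d.pop("weights", None)  # bulky; logged as a count instead
    return d


def run_pipeline(
    design: StudyDesign,
    blocks: dict,
    meta: FeatureMetaMap,
    pathways: PathwayMap | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute the full analysis on in-memory inputs.

    ``blocks`` maps block names to OmicsBlocks; a "metabolome" block is
    required, "proteome"/"transcriptome" are each optional.
    """
    config = config or PipelineConfig()
    if "metabolome" not in blocks:
        raise ValueError("pipeline stage preprocess: a metabolome block is required")
    metabolome = blocks["metabolome"]

    # -- preprocess (untargeted LC-MS housekeeping) ------------------------
    if config.run_preprocess and config.preprocess is not None:
        try:
            pp = config.preprocess
            metabolome = blank_filter(metabolome, design, pp)
            metabolome = qc_cv_filter(metabolome, design, pp)
            if pp.weights:
                metabolome = weight_normalize(metabolome, pp)
        except ValueError as err:
            raise ValueError(f"pipeline stage preprocess: {err}") from err

    # restrict everything to shared biological samples
    work = {"metabolome": metabolome}
    for name in ("proteome", "transcriptome"):
        if name in blocks:
            work[name] = blocks[name]
    names = list(work)
    aligned = align_blocks(list(work.values()), design)
    work = dict(zip(names, aligned))
    metabolome = work["metabolome"]

    # -- PCA overview ------------------------------------------------------
    pca_scores, _pca_loadings, pca_var = overview_pca(metabolome)

    # -- satellite collapsing & peptide flagging ---------------------------
    collapse_report = None
    peptide_flags: set = set()
    if config.run_collapse:
        try:
            peptide_flags = flag_peptides(metabolome, meta, config.redundancy)
            collapse_report = collapse_block(metabolome, meta, config.redundancy)
            metabolome = collapse_report.collapsed
            work["metabolome"] = metabolome
        except ValueError as err:
            raise ValueError(f"pipeline stage collapse: {err}") from err

    # -- stability selection ----------------------------------------------
    stability: dict[str, StabilityResult] = {}
    for name, block in work.items():
        params = config.stability.get(name, StabilityParams())
        try:
            stability[name] = compute_stability(block, design, params)
        except ValueError as err:
            raise ValueError(f"pipeline stage stability[{name}]: {err}") from err
    stable_metabolites = [
        f for f in stability["metabolome"].selected_ids if f not in peptide_flags
    ]

    # -- sPLS covariation + enrichment of the groups -----------------------
    spls_models: dict[str, SplsModel] = {}
    groups: dict[str, list] = {}
    group_enrichment: dict[tuple, pd.DataFrame] = {}
    if config.run_spls and stable_metabolites:
        Y = metabolome.subset_features(stable_metabolites)
        for name in ("proteome", "transcriptome"):
            if name not in work:
                continue
            try:
                model = fit_spls(work[name], Y, config.spls)
            except ValueError as err:
                raise ValueError(f"pipeline stage spls[{name}]: {err}") from err
            spls_models[name] = model
            groups[name] = group_by_loading(model, config.loading_threshold)
            if config.run_enrichment:
                background = set(work[name].feature_ids)
                for group in groups[name]:
                    sel = set(group.x_members)
                    if not sel:
                        continue
                    group_enrichment[(name, group.label)] = fisher_enrichment(
                        sel, background, meta, config.enrichment
                    )

    # -- per-metabolite screens -------------------------------------------
    screen_summary = screen_records = pathway_tables = None
    if config.run_screens and stable_metabolites:
        summaries, records = [], []
        for met in stable_metabolites:
            values = metabolome.data.loc[met]
            for name in ("proteome", "transcriptome"):
                if name not in work:
                    continue
                recs, summary = screen_metabolite(
                    met, values, work[name], meta, config.screen
                )
                recs = recs.assign(block=name)
                records.append(recs)
                summaries.append(
                    {
                        "metabolite_id": met,
                        "block": name,
                        "n_correlated": summary.n_correlated,
                        "n_assigned": summary.n_assigned,
                        "reportable": summary.reportable,
                        "largest_bin": summary.largest_bin or "",
                        "largest_bin_count": summary.largest_bin_count,
                    }
                )
        screen_summary = pd.DataFrame(summaries)
        screen_records = (
            pd.concat(records, ignore_index=True) if records else pd.DataFrame()
        )
        if pathways:
            tables = []
            other = [work[n] for n in ("proteome", "transcriptome") if n in work]
            for met, members in pathways.items():
                if met not in metabolome.data.index:
                    logger.info("pathway metabolite %s absent from block; skipped", met)
                    continue
                _ranked, filtered = pathway_correlations(
                    met, metabolome.data.loc[met], members, other, meta, config.screen
                )
                tables.append(filtered)
            pathway_tables = (
                pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
            )

    provenance = {
        "version": __version__,
        "n_biological_samples": len(design.biological_samples),
        "blocks": {n: list(b.data.shape) for n, b in work.items()},
        "stability_thresholds": {
            n: _params_dict(p) for n, p in config.stability.items()
        },
        "preprocess": _params_dict(config.preprocess),
        "redundancy": _params_dict(config.redundancy),
        "spls": _params_dict(config.spls),
        "screen": _params_dict(config.screen),
        "enrichment": _params_dict(config.enrichment),
        "loading_threshold": config.loading_threshold,
        "stages_run": {
            "preprocess": bool(config.run_preprocess and config.preprocess),
            "collapse": config.run_collapse,
            "spls": config.run_spls,
            "screens": config.run_screens,
            "enrichment": config.run_enrichment,
        },
    }
    return PipelineResult(
        config=config,
        pca_scores=pca_scores,
        pca_variance_pct=pca_var,
        collapse=collapse_report,
        peptide_flags=peptide_flags,
        stability=stability,
        stable_metabolites=stable_metabolites,
        spls_models=spls_models,
        covariation_groups=groups,
        group_enrichment=group_enrichment,
        screen_summary=screen_summary,
        screen_records=screen_records,
        pathway_tables=pathway_tables,
        provenance=provenance,
    )


def write_report(result: PipelineResult, meta: FeatureMetaMap, out_dir: str | Path) -> None:
    """Write the report bundle: stable tables, groups, screens, provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"variance_pct": np.round(result.pca_variance_pct, 4)},
        index=[f"PC{i + 1}" for i in range(len(result.pca_variance_pct))],
    ).to_csv(out / "pca_variance.tsv", sep="\t", index_label="component")
    result.pca_scores.round(4).to_csv(out / "pca_scores.tsv", sep="\t", index_label="sample_id")
    for name, res in result.stability.items():
        stability_table(res, meta, selected_only=False).to_csv(
            out / f"stability_{name}.tsv", sep="\t", index_label="feature_id"
        )
        stability_table(res, meta, selected_only=True).to_csv(
            out / f"stable_{name}.tsv", sep="\t", index_label="feature_id"
        )
    if result.collapse is not None:
        result.collapse.clusters.to_csv(out / "collapse_report.tsv", sep="\t", index=False)
    for name, groups in result.covariation_groups.items():
        rows = [
            {"group": g.label, "component": g.component, "sign": g.sign,
             "member": m, "side": side}
            for g in groups
            for side, members in (("metabolite", g.y_members), (name, g.x_members))
            for m in members
        ]
        pd.DataFrame(rows).to_csv(out / f"groups_{name}.tsv", sep="\t", index=False)
    for (name, label), df in result.group_enrichment.items():
        df.to_csv(out / f"enrichment_{name}_{label.replace('+', 'pos').replace('-', 'neg')}.tsv",
                  sep="\t", index=False)
    if result.screen_summary is not None:
        result.screen_summary.to_csv(out / "screen_summary.tsv", sep="\t", index=False)
    if result.screen_records is not None and len(result.screen_records):
        result.screen_records.to_csv(out / "screen_records.tsv", sep="\t", index=False)
    if result.pathway_tables is not None and len(result.pathway_tables):
        result.pathway_tables.to_csv(out / "pathway_correlations.tsv", sep="\t", index=False)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(result.provenance, fh, indent=1, sort_keys=True)
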