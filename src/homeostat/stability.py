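"""Hierarchical coefficient-of-variation stability selection.

Two CV strata over a stage x truss design:

* **between-truss CV** — within each stage, the CV across trusses; the
  feature's value is the mean of these per-stage CVs over all usable
  stages (a stage is usable with >=2 present values).
* **between-stage CV** — the CV of the per-stage truss means.

A feature is "most stable" when both CVs fall below their thresholds
(25% is the conventional default; relaxed to 40% for transcriptomes,
where dispersion is higher).  CVs use the sample standard deviation
(n-1) and are undefined (NaN) on fewer than two values or a
non-positive mean; undefined features are never selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_model import FeatureMetaMap, OmicsBlock, StudyDesign

logger = logging.getLogger(__name__)


@dataclass
class StabilityParams:
    """Dual CV thresholds (percent) and boundary convention."""

    cv_truss_max: float = 25.0
    cv_stage_max: float = 25.0
    strict: bool = True  # True: selected iff CV < threshold (printed wording)

    def __post_init__(self) -> None:
        if self.cv_truss_max <= 0 or self.cv_stage_max <= 0:
            raise ValueError("CV thresholds must be positive")


def cv(values) -> float:
    """Percent coefficient of variation, sample sd / mean * 100.

    NaN when fewer than two present values or when the mean is not
    strictly positive (undefined on the abundance scale).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m <= 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / m)


def between_truss_cv(values: pd.Series, design: StudyDesign) -> tuple[float, int]:
    """Mean over stages of the within-stage across-truss CV.

    ``values`` is indexed by sample id.  Returns (cv_percent, n_stages_used);
    stages with <2 present values (or a non-positive mean) are excluded.
    """
    per_stage = []
    for _stage, samples in design.stage_groups(list(values.index)).items():
        c = cv(values.loc[samples])
        if not np.isnan(c):
            per_stage.append(c)
    if not per_stage:
        return float("nan"), 0
    return float(np.mean(per_stage)), len(per_stage)


def between_stage_cv(values: pd.Series, design: StudyDesign) -> tuple[float, int]:
    """CV of the per-stage truss means; (cv_percent, n_stages_used)."""
    means = []
    for _stage, samples in design.stage_groups(list(values.index)).items():
        v = values.loc[samples].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        if v.size:
            means.append(v.mean())
    if len(means) < 2:
        return float("nan"), len(means)
    return cv(means), len(means)


@dataclass
class StabilityResult:
    """Per-feature CVs and selection flags.

    ``table`` is indexed by feature_id with columns cv_truss, cv_stage,
    n_stages_used, selected.
    """

    table: pd.DataFrame
    params: StabilityParams

    @property
    def selected_ids(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


def _stage_stats(block: OmicsBlock, design: StudyDesign):
    """Vectorized per-stage counts, means and sds (features x stages)."""
    groups = design.stage_groups(block.sample_ids)
    stages = list(groups)
    values = block.data.to_numpy(dtype=float)
    cols = {s: i for i, s in enumerate(block.sample_ids)}
    n = np.empty((values.shape[0], len(stages)))
    mean = np.empty_like(n)
    sd = np.empty_like(n)
    import warnings as _warnings

    for j, stage in enumerate(stages):
        idx = [cols[s] for s in groups[stage]]
        sub = values[:, idx]
        present = ~np.isnan(sub)
        n[:, j] = present.sum(axis=1)
        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mean[:, j] = np.nanmean(np.where(present, sub, np.nan), axis=1)
            sd[:, j] = np.nanstd(np.where(present, sub, np.nan), axis=1, ddof=1)
    return stages, n, mean, sd


def compute_stability(
    block: OmicsBlock, design: StudyDesign, params: StabilityParams | None = None
) -> StabilityResult:
    """Both CV strata and the dual-threshold selection flag, per feature."""
    params = params or StabilityParams()
    if len(design.stages) < 2 or len(design.trusses) < 2:
        raise ValueError("CV analyses need >=2 stages and >=2 trusses in the design")
    _stages, n, mean, sd = _stage_stats(block, design)

    with np.errstate(invalid="ignore", divide="ignore"):
        stage_cv = 100.0 * sd / mean
    stage_cv[(n < 2) | ~(mean > 0)] = np.nan
    usable = ~np.isnan(stage_cv)
    n_stages_used = usable.sum(axis=1)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        cv_truss = np.nanmean(np.where(usable, stage_cv, np.nan), axis=1)
    cv_truss[n_stages_used == 0] = np.nan

    stage_means = np.where(n >= 1, mean, np.nan)
    n_means = (~np.isnan(stage_means)).sum(axis=1)
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        grand = np.nanmean(stage_means, axis=1)
        spread = np.nanstd(stage_means, axis=1, ddof=1)
        cv_stage = 100.0 * spread / grand
    cv_stage[(n_means < 2) | ~(grand > 0)] = np.nan

    if params.strict:
        selected = (cv_truss < params.cv_truss_max) & (cv_stage < params.cv_stage_max)
    else:
        selected = (cv_truss <= params.cv_truss_max) & (cv_stage <= params.cv_stage_max)
    selected &= ~np.isnan(cv_truss) & ~np.isnan(cv_stage)

    n_undef = int(np.isnan(cv_truss).sum() + np.isnan(cv_stage).sum())
    if n_undef:
        logger.info("block %s: %d undefined CV entries (excluded from selection)", block.name, n_undef)

    table = pd.DataFrame(
        {
            "cv_truss": cv_truss,
            "cv_stage": cv_stage,
            "n_stages_used": n_stages_used.astype(int),
            "selected": selected,
        },
        index=pd.Index(block.feature_ids, name="feature_id"),
    )
    return StabilityResult(table, params)


def select_stable(
    block: OmicsBlock, design: StudyDesign, params: StabilityParams | None = None
) -> StabilityResult:
    """Alias of :func:`compute_stability`; named for the selection step."""
    return compute_stability(block, design, params)


@dataclass
class CategoryCvProfile:
    categories: pd.DataFrame  # category, n_members, mean_cv_truss, mean_cv_stage
    pairwise: pd.DataFrame  # metric, cat_a, cat_b, statistic, p, q, significant


def category_cv_profile(
    result: StabilityResult,
    meta: FeatureMetaMap,
    level: int = 1,
    min_members: int = 3,
    alpha: float = 0.01,
) -> CategoryCvProfile:
    """Per-category mean CVs with all pairwise Wilcoxon rank-sum tests.

    Features are grouped by their BIN prefix at ``level`` (top-level by
    default).  For each CV stratum, every category pair is compared with a
    two-sample Wilcoxon rank-sum test on the member CV distributions;
    p-values are Benjamini-Hochberg corrected across pairs within a
    stratum and flagged significant at corrected p < ``alpha``.
    """
    groups: dict[str, list[str]] = {}
    for fid in result.table.index:
        m = meta.get(fid)
        if m is None:
            continue
        cat = m.bin_prefix(level)
        if cat is None:
            continue
        groups.setdefault(cat, []).append(fid)
    kept = {}
    for cat, ids in sorted(groups.items()):
        if len(ids) < min_members:
            logger.info("category %s has %d members (<%d); excluded", cat, len(ids), min_members)
            continue
        kept[cat] = ids
    if len(kept) < 2:
        raise ValueError("need >=2 categories with enough members for a CV profile")

    cat_rows = []
    for cat, ids in kept.items():
        sub = result.table.loc[ids]
        cat_rows.append(
            {
                "category": cat,
                "n_members": len(ids),
                "mean_cv_truss": float(sub["cv_truss"].mean()),
                "mean_cv_stage": float(sub["cv_stage"].mean()),
            }
        )
    categories = pd.DataFrame(cat_rows).set_index("category")

    pair_rows = []
    cats = list(kept)
    for metric in ("cv_truss", "cv_stage"):
        tests = []
        for i, a in enumerate(cats):
            for b in cats[i + 1 :]:
                xa = result.table.loc[kept[a], metric].dropna()
                xb = result.table.loc[kept[b], metric].dropna()
                res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
                tests.append((a, b, float(res.statistic), float(res.pvalue)))
        qs = multipletests([t[3] for t in tests], method="fdr_bh")[1]
        for (a, b, stat, p), q in zip(tests, qs):
            pair_rows.append(
                {
                    "metric": metric,
                    "cat_a": a,
                    "cat_b": b,
                    "statistic": stat,
                    "p": p,
                    "q": float(q),
                    "significant": bool(q < alpha),
                }
            )
    return CategoryCvProfile(categories, pd.DataFrame(pair_rows))


def stability_table(
    result: StabilityResult, meta: FeatureMetaMap | None = None, selected_only: bool = True
) -> pd.DataFrame:
    """Report table: feature, CVs, annotation and BIN (Table 1/2 shape)."""
    table = result.table[result.table["selected"]] if selected_only else result.table
    out = table[["cv_stage", "cv_truss"]].round(2).copy()
    out.columns = ["cv_between_stages", "cv_between_trusses"]
    if meta:
        out["annotated"] = [int(meta[f].annotated) if f in meta else 0 for f in out.index]
        out["bin_path"] = [meta[f].bin_path or "" if f in meta else "" for f in out.index]
    return out
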