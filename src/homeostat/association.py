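"""Per-metabolite Spearman correlation screens.

Two complementary screens:

* **unfocused screen** — one metabolite against every feature of an
  omics block, keeping pairs at a stringent p < 1e-4 with no multiple
  testing correction (a deliberate choice: correcting would act
  differently on blocks of very different width; an optional BH column
  is available anyway).  A metabolite is "reportable" when at least
  ``min_assigned`` annotated ("assigned") targets pass.
* **pathway screen** — a metabolite against the proteins/transcripts of
  its known pathways: members are ranked by |rho|, the top k kept (ties
  at the boundary included), then filtered at p < 1e-3 for the listing.

rho is computed on average-ranked data over pairwise-complete samples;
the two-sided p-value uses the t approximation with n-2 df.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_model import FeatureMetaMap, OmicsBlock

logger = logging.getLogger(__name__)


@dataclass
class ScreenParams:
    alpha_unfocused: float = 1e-4
    alpha_pathway: float = 1e-3
    top_k: int = 10
    min_assigned: int = 10
    add_bh_column: bool = False

    def __post_init__(self) -> None:
        for a in (self.alpha_unfocused, self.alpha_pathway):
            if not 0 < a < 1:
                raise ValueError("alpha must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


def spearman(x, y) -> tuple[float, float]:
    """(rho, two-sided p) on pairwise-complete samples; NaN when undefined.

    Needs >=4 shared present values; constant vectors give NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    shared = ~np.isnan(x) & ~np.isnan(y)
    if shared.sum() < 4:
        return float("nan"), float("nan")
    xs, ys = x[shared], y[shared]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(xs, ys)
    return float(res.statistic), float(res.pvalue)


def _t_sf_two_sided(rho: np.ndarray, n: int) -> np.ndarray:
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    return np.minimum(p, 1.0)


def spearman_screen(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman of one vector against the rows of a matrix.

    Complete-case fast path (rank transform + matrix product); rows with
    missing entries fall back to the pairwise-complete scalar routine.
    Returns (rho, p) arrays; constant rows give NaN.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.size
    rho = np.full(X.shape[0], np.nan)
    p = np.full(X.shape[0], np.nan)
    y_ok = ~np.isnan(y)
    row_complete = ~np.isnan(X).any(axis=1)

    if y_ok.all() and n >= 4:
        comp = row_complete.copy()
        if comp.any():
            ry = stats.rankdata(y)
            rX = stats.rankdata(X[comp], axis=1)
            ry_c = ry - ry.mean()
            rX_c = rX - rX.mean(axis=1, keepdims=True)
            denom = np.sqrt((rX_c**2).sum(axis=1) * (ry_c**2).sum())
            ok = denom > 0
            r = np.full(comp.sum(), np.nan)
            r[ok] = (rX_c @ ry_c)[ok] / denom[ok]
            rho[comp] = r
            p[comp] = np.where(np.isnan(r), np.nan, _t_sf_two_sided(r, n))
        rest = np.flatnonzero(~comp)
    else:
        rest = np.arange(X.shape[0])
    for i in rest:
        rho[i], p[i] = spearman(y, X[i])
    return rho, p


@dataclass
class ScreenSummary:
    metabolite_id: str
    n_correlated: int
    n_assigned: int
    reportable: bool
    largest_bin: str | None  # top-level BIN with the most assigned hits (>2 required)
    largest_bin_count: int


def screen_metabolite(
    metabolite_id: str,
    metabolite_values: pd.Series,
    block: OmicsBlock,
    meta: FeatureMetaMap,
    params: ScreenParams | None = None,
) -> tuple[pd.DataFrame, ScreenSummary]:
    """Unfocused screen of one metabolite against a whole omics block."""
    params = params or ScreenParams()
    y = metabolite_values.loc[block.sample_ids].to_numpy(dtype=float)
    rho, p = spearman_screen(y, block.data.to_numpy(dtype=float))
    hit = p < params.alpha_unfocused  # NaN p never passes
    records = pd.DataFrame(
        {
            "metabolite_id": metabolite_id,
            "target_id": np.asarray(block.feature_ids)[hit],
            "rho": rho[hit],
            "p": p[hit],
        }
    )
    records["target_annotated"] = [
        bool(meta[t].annotated) if t in meta else False for t in records["target_id"]
    ]
    records["target_bin"] = [
        (meta[t].bin_path or "") if t in meta else "" for t in records["target_id"]
    ]
    if params.add_bh_column and len(p):
        valid = ~np.isnan(p)
        q = np.full_like(p, np.nan)
        if valid.any():
            q[valid] = multipletests(p[valid], method="fdr_bh")[1]
        records["q_bh"] = q[hit]

    assigned = records[records["target_annotated"]]
    largest_bin, largest_count = None, 0
    if len(assigned):
        top_bins = (
            assigned["target_bin"].map(lambda b: b.split(".")[0] if b else "")
        )
        counts = top_bins[top_bins != ""].value_counts()
        counts = counts[counts > 2]  # only bins with more than two assigned members
        if len(counts):
            largest_bin = str(counts.index[0])
            largest_count = int(counts.iloc[0])
    summary = ScreenSummary(
        metabolite_id=metabolite_id,
        n_correlated=int(len(records)),
        n_assigned=int(len(assigned)),
        reportable=bool(len(assigned) >= params.min_assigned),
        largest_bin=largest_bin,
        largest_bin_count=largest_count,
    )
    return records, summary


def pathway_correlations(
    metabolite_id: str,
    metabolite_values: pd.Series,
    members: list[str],
    blocks: list[OmicsBlock],
    meta: FeatureMetaMap,
    params: ScreenParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pathway-restricted screen; returns (ranked, filtered) record tables.

    Per target type (block), members are ranked by |rho| and the top_k
    kept (|rho| ties at rank k are all retained); the filtered table then
    applies the p < alpha_pathway listing threshold.
    """
    params = params or ScreenParams()
    member_set = set(members)
    rows = []
    resolved: set[str] = set()
    for block in blocks:
        ids = [f for f in block.feature_ids if f in member_set]
        resolved.update(ids)
        for fid in ids:
            rho, p = spearman(
                metabolite_values.loc[block.sample_ids].to_numpy(dtype=float),
                block.data.loc[fid].to_numpy(dtype=float),
            )
            if np.isnan(rho):
                logger.info("pathway member %s constant/undefined; excluded", fid)
                continue
            m = meta.get(fid)
            rows.append(
                {
                    "metabolite_id": metabolite_id,
                    "target_id": fid,
                    "target_type": block.name,
                    "rho": rho,
                    "p": p,
                    "target_annotated": bool(m.annotated) if m else False,
                    "target_bin": (m.bin_path or "") if m else "",
                }
            )
    unresolved = member_set - resolved
    if unresolved:
        logger.info(
            "metabolite %s: %d pathway members not found in any block",
            metabolite_id,
            len(unresolved),
        )
    if not rows:
        empty = pd.DataFrame(
            columns=["metabolite_id", "target_id", "target_type", "rho", "p",
                     "target_annotated", "target_bin"]
        )
        return empty, empty.copy()
    ranked_parts = []
    all_rows = pd.DataFrame(rows)
    for _type, sub in all_rows.groupby("target_type", sort=True):
        sub = sub.reindex(sub["rho"].abs().sort_values(ascending=False).index)
        if len(sub) > params.top_k:
            cutoff = sub["rho"].abs().iloc[params.top_k - 1]
            sub = sub[sub["rho"].abs() >= cutoff]  # keep boundary ties
        ranked_parts.append(sub)
    ranked = pd.concat(ranked_parts, ignore_index=True)
    filtered = ranked[ranked["p"] < params.alpha_pathway].reset_index(drop=True)
    return ranked, filtered
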