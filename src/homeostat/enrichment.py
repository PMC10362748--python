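"""Over/under-representation of hierarchical functional categories.

PageMan-style one-tailed hypergeometric (Fisher) tests of a selected
feature set against a measured background, per category and per BIN
depth, with Benjamini-Hochberg correction across the categories of a
level.  Features without an annotation form an explicit "unannotated"
pseudo-category, which can itself be over- or under-represented.

The display statistic is a signed probit of the smaller tail,
z = +Phi^-1(1-p_over) for over-representation and -Phi^-1(1-p_under)
for under-representation; it affects colouring only, never p or q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_model import FeatureMetaMap

UNANNOTATED = "unannotated"


@dataclass
class EnrichmentParams:
    direction: str = "both"  # over | under | both
    correct: bool = True  # FDR drives the significance column
    alpha: float = 0.05
    min_category: int = 1
    levels: tuple[int, ...] = (1,)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.direction not in ("over", "under", "both"):
            raise ValueError("direction must be over, under or both")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _categories_at_level(
    ids, meta: FeatureMetaMap, level: int
) -> dict[str, set[str]]:
    cats: dict[str, set[str]] = {}
    for fid in ids:
        m = meta.get(fid)
        if m is None or not m.annotated or not m.bin_path:
            cats.setdefault(UNANNOTATED, set()).add(fid)
        else:
            cats.setdefault(m.bin_prefix(level), set()).add(fid)
    return cats


def fisher_enrichment(
    selected: set[str],
    background: set[str],
    meta: FeatureMetaMap,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """Hypergeometric over/under tails per category and level, BH per level.

    ``selected`` must be a subset of ``background``.  Returns one row per
    (level, category): counts, p_over, p_under, q_over, q_under, q,
    z_display and the significance flag driven by ``direction`` and
    ``correct``.
    """
    params = params or EnrichmentParams()
    if not selected <= background:
        raise ValueError("selected set is not a subset of the background")
    n_bg = len(background)
    n_sel = len(selected)
    rows = []
    for level in params.levels:
        bg_cats = _categories_at_level(background, meta, level)
        level_rows = []
        for cat in sorted(bg_cats):
            members = bg_cats[cat]
            if len(members) < params.min_category:
                continue
            k = len(members & selected)
            K = len(members)
            p_over = float(stats.hypergeom.sf(k - 1, n_bg, K, n_sel))
            p_under = float(stats.hypergeom.cdf(k, n_bg, K, n_sel))
            level_rows.append(
                {
                    "level": level,
                    "bin_path": cat,
                    "in_set": k,
                    "set_size": n_sel,
                    "in_background": K,
                    "background_size": n_bg,
                    "p_over": p_over,
                    "p_under": p_under,
                }
            )
        if not level_rows:
            continue
        df = pd.DataFrame(level_rows)
        df["q_over"] = bh_adjust(df["p_over"])
        df["q_under"] = bh_adjust(df["p_under"])
        if params.direction == "over":
            p_primary, q_primary = df["p_over"], df["q_over"]
        elif params.direction == "under":
            p_primary, q_primary = df["p_under"], df["q_under"]
        else:
            p_primary = np.minimum(1.0, 2.0 * np.minimum(df["p_over"], df["p_under"]))
            q_primary = bh_adjust(p_primary)
        df["p"] = p_primary
        df["q"] = q_primary
        over_is_smaller = df["p_over"] <= df["p_under"]
        tail = np.where(over_is_smaller, df["p_over"], df["p_under"])
        z = stats.norm.ppf(1.0 - np.clip(tail, 1e-300, 1.0))
        df["z_display"] = np.where(over_is_smaller, z, -z)
        crit = df["q"] if params.correct else df["p"]
        df["significant"] = crit < params.alpha
        rows.append(df)
    if not rows:
        raise ValueError("no category passed min_category at any level")
    return pd.concat(rows, ignore_index=True)
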