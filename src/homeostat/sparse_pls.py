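"""Two-block sparse PLS (regression mode) with soft-thresholded loadings.

The model seeks pairs of latent scores t = Xu, s = Yv maximizing the
cross-block covariance u' X'Y v, with an L1 (soft-threshold) penalty on
the X-weight vector so that exactly ``keepX`` predictors survive per
component.  Deflation is in regression mode: both X and Y are deflated
by regression on the X-score, so Y acts as the response block.  Scores
from successive components are therefore orthogonal.

Variable-score correlations (the bounded correlation-circle coordinates)
are used for the covariation grouping at the |r| > 0.6 convention: raw
loading vectors are scale-dependent, while correlations put both blocks
on one bounded plot.

Initialization is the leading singular pair of X'Y with a fixed sign
convention (largest-magnitude X-weight positive), making fits bit-stable
across runs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_model import OmicsBlock

logger = logging.getLogger(__name__)


@dataclass
class SplsParams:
    ncomp: int = 2
    select_ratio: float = 10.0  # X variables kept per Y variable, split over components
    max_iter: int = 500
    tol: float = 1e-9
    keepX: list[int] | None = None  # explicit per-component override

    def __post_init__(self) -> None:
        if self.ncomp < 1:
            raise ValueError("ncomp must be >= 1")
        if self.select_ratio <= 0:
            raise ValueError("select_ratio must be positive")


@dataclass
class SplsModel:
    x_scores: pd.DataFrame  # samples x ncomp
    y_scores: pd.DataFrame
    x_loadings: pd.DataFrame  # sparse X weight vectors, variables x ncomp
    y_loadings: pd.DataFrame
    x_varcorr: pd.DataFrame  # variable-score correlations, bounded [-1, 1]
    y_varcorr: pd.DataFrame
    keepX: list[int]
    dropped_x: list[str]
    dropped_y: list[str]

    def selected_x_per_component(self) -> list[list[str]]:
        return [
            list(self.x_loadings.index[self.x_loadings.iloc[:, c] != 0.0])
            for c in range(self.x_loadings.shape[1])
        ]


def _as_matrix(block) -> pd.DataFrame:
    """Accept an OmicsBlock (features x samples) or DataFrame (samples x vars)."""
    if isinstance(block, OmicsBlock):
        return block.data.T
    return block


def _standardize(mat: pd.DataFrame, label: str) -> tuple[np.ndarray, list[str], list[str]]:
    values = mat.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = list(mat.columns[~keep])
    if dropped:
        logger.info("%s block: dropped %d constant columns", label, len(dropped))
    z = (values[:, keep] - mean[keep]) / sd[keep]
    return z, list(mat.columns[keep]), dropped


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold so the ``keep`` largest-magnitude entries stay nonzero."""
    if keep >= w.size:
        return w
    lam = np.sort(np.abs(w))[-(keep + 1)]  # magnitude of the (keep+1)-th largest
    return np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)


def fit_spls(X, Y, params: SplsParams | None = None) -> SplsModel:
    """Fit the sparse PLS; X and Y must be column-aligned on samples.

    keepX defaults to ceil(select_ratio * |Y variables| / ncomp) per
    component, clamped (with a warning) to the number of X variables.
    """
    params = params or SplsParams()
    Xm, Ym = _as_matrix(X), _as_matrix(Y)
    if list(Xm.index) != list(Ym.index):
        raise ValueError("X and Y are not aligned on the same samples")
    n = Xm.shape[0]
    Xc, x_ids, dropped_x = _standardize(Xm, "X")
    Yc, y_ids, dropped_y = _standardize(Ym, "Y")
    p, q = Xc.shape[1], Yc.shape[1]

    if params.keepX is not None:
        keepX = list(params.keepX)
        if len(keepX) != params.ncomp:
            raise ValueError("explicit keepX must have ncomp entries")
    else:
        keepX = [math.ceil(params.select_ratio * q / params.ncomp)] * params.ncomp
    for c, k in enumerate(keepX):
        if k > p:
            warnings.warn(f"keepX[{c}]={k} exceeds {p} X variables; clamped", stacklevel=2)
            keepX[c] = p

    X0, Y0 = Xc.copy(), Yc.copy()  # kept for variable-score correlations
    x_scores = np.empty((n, params.ncomp))
    y_scores = np.empty((n, params.ncomp))
    u_all = np.zeros((p, params.ncomp))
    v_all = np.zeros((q, params.ncomp))

    for c in range(params.ncomp):
        M = Xc.T @ Yc
        # SVD-based initialization: leading right singular vector of M
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        v = vt[0]
        u = np.zeros(p)
        converged = False
        for _ in range(params.max_iter):
            u_new = _soft_threshold_keep(M @ v, keepX[c])
            nrm = np.linalg.norm(u_new)
            if nrm == 0:
                raise ValueError("sparse weight vector collapsed to zero")
            u_new /= nrm
            v_new = M.T @ u_new
            v_new /= np.linalg.norm(v_new)
            delta = min(np.linalg.norm(u_new - u), np.linalg.norm(u_new + u))
            u, v = u_new, v_new
            if delta < params.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"component {c + 1}: no convergence in {params.max_iter} iterations; "
                "keeping last iterate",
                stacklevel=2,
            )
        # fixed sign convention: largest-magnitude X weight positive
        if u[np.argmax(np.abs(u))] < 0:
            u, v = -u, -v
        xi = Xc @ u
        omega = Yc @ v
        u_all[:, c], v_all[:, c] = u, v
        x_scores[:, c], y_scores[:, c] = xi, omega
        # regression-mode deflation: both blocks regressed on the X score
        denom = xi @ xi
        Xc = Xc - np.outer(xi, (Xc.T @ xi) / denom)
        Yc = Yc - np.outer(xi, (Yc.T @ xi) / denom)

    def _corr(block0: np.ndarray) -> np.ndarray:
        zb = (block0 - block0.mean(axis=0)) / block0.std(axis=0, ddof=1)
        zt = (x_scores - x_scores.mean(axis=0)) / x_scores.std(axis=0, ddof=1)
        return zb.T @ zt / (n - 1)

    comps = [f"comp{c + 1}" for c in range(params.ncomp)]
    return SplsModel(
        x_scores=pd.DataFrame(x_scores, index=Xm.index, columns=comps),
        y_scores=pd.DataFrame(y_scores, index=Ym.index, columns=comps),
        x_loadings=pd.DataFrame(u_all, index=x_ids, columns=comps),
        y_loadings=pd.DataFrame(v_all, index=y_ids, columns=comps),
        x_varcorr=pd.DataFrame(_corr(X0), index=x_ids, columns=comps),
        y_varcorr=pd.DataFrame(_corr(Y0), index=y_ids, columns=comps),
        keepX=keepX,
        dropped_x=dropped_x,
        dropped_y=dropped_y,
    )


def select_covarying(model: SplsModel) -> set[str]:
    """Union over components of the X variables with nonzero loadings."""
    selected: set[str] = set()
    for ids in model.selected_x_per_component():
        selected.update(ids)
    return selected


@dataclass(frozen=True)
class CovariationGroup:
    component: int  # 1-based
    sign: int  # +1 / -1
    y_members: tuple[str, ...]
    x_members: tuple[str, ...]

    @property
    def label(self) -> str:
        return f"comp{self.component}{'+' if self.sign > 0 else '-'}"

    @property
    def members(self) -> tuple[str, ...]:
        return self.y_members + self.x_members


def group_by_loading(model: SplsModel, threshold: float = 0.6) -> list[CovariationGroup]:
    """Covariation groups from variable-score correlations.

    A variable joins the (component, sign) group of its largest-magnitude
    correlation, provided |r| exceeds ``threshold``; only sparsely
    selected X variables are eligible.  Empty groups are dropped.
    """
    selected = select_covarying(model)
    buckets: dict[tuple[int, int], dict[str, list[str]]] = {}

    def assign(varcorr: pd.DataFrame, var_id: str, side: str) -> None:
        row = varcorr.loc[var_id].to_numpy()
        c = int(np.argmax(np.abs(row)))
        if abs(row[c]) > threshold:
            key = (c + 1, 1 if row[c] > 0 else -1)
            buckets.setdefault(key, {"y": [], "x": []})[side].append(var_id)

    for var_id in model.y_varcorr.index:
        assign(model.y_varcorr, var_id, "y")
    for var_id in model.x_varcorr.index:
        if var_id in selected:
            assign(model.x_varcorr, var_id, "x")

    return [
        CovariationGroup(comp, sign, tuple(b["y"]), tuple(b["x"]))
        for (comp, sign), b in sorted(buckets.items())
        if b["y"] or b["x"]
    ]
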