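"""Rule-based collapsing of untargeted LC-MS satellite signatures.

An electrospray source emits several features per compound: 13C
isotopologues, alkali/ammonium adducts and in-source fragments, all
co-eluting with and intensity-correlated to the parent ion.  Counting
each as a metabolite inflates any downstream tally, so satellites are
detected from (delta m/z, retention-time, correlation) rules, clustered
by connected components, and each cluster is reduced to one
representative row.  Doubly-charged isotope spacing (~0.5017 Th) flags
peptide-like features, which are excluded from metabolite-level results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_model import FeatureMetaMap, OmicsBlock

logger = logging.getLogger(__name__)

KIND_ISOTOPE = "isotope"
KIND_ADDUCT = "adduct"
KIND_FRAGMENT = "fragment_loss"


@dataclass(frozen=True)
class DeltaRule:
    """A known m/z offset between a parent and a satellite feature."""

    name: str
    delta_mz: float  # Th; positive = satellite heavier, negative = neutral loss
    kind: str
    charge: int = 1


#: Positive-mode ESI rule table: 13C isotope, common adducts relative to
#: [M+H]+, and frequent neutral losses.  User-extensible.
DEFAULT_RULES: tuple[DeltaRule, ...] = (
    DeltaRule("isotope_13C", 1.00335, KIND_ISOTOPE, 1),
    DeltaRule("adduct_Na", 21.98194, KIND_ADDUCT, 1),
    DeltaRule("adduct_K", 37.95588, KIND_ADDUCT, 1),
    DeltaRule("adduct_NH4", 17.02655, KIND_ADDUCT, 1),
    DeltaRule("loss_H2O", -18.01056, KIND_FRAGMENT, 1),
    DeltaRule("loss_HCOOH", -46.00548, KIND_FRAGMENT, 1),
)


@dataclass
class RedundancyParams:
    rt_tol: float = 5.0  # seconds
    corr_min: float = 0.9  # Spearman rho on shared present samples
    mz_tol: float = 0.01  # Th
    isotope_spacing_z2: float = 0.5017  # Th, doubly-charged isotope spacing

    def __post_init__(self) -> None:
        for name in ("rt_tol", "corr_min", "mz_tol", "isotope_spacing_z2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SatelliteEdge:
    parent: str
    satellite: str
    rule: str
    kind: str
    rho: float


def read_rules(path: str | Path) -> tuple[DeltaRule, ...]:
    df = pd.read_csv(path, sep="\t")
    return tuple(
        DeltaRule(r.name, float(r.delta_mz), r.kind, int(r.charge))
        for r in df.itertuples(index=False)
    )


def write_rules(rules: tuple[DeltaRule, ...], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"name": r.name, "delta_mz": f"{r.delta_mz:.5f}", "kind": r.kind, "charge": r.charge}
            for r in rules
        ]
    ).to_csv(path, sep="\t", index=False)


def _spearman_rho(a: np.ndarray, b: np.ndarray) -> float:
    shared = ~np.isnan(a) & ~np.isnan(b)
    if shared.sum() < 4:
        return float("nan")
    return float(stats.spearmanr(a[shared], b[shared]).statistic)


def _ms_features(block: OmicsBlock, meta: FeatureMetaMap):
    feats = []
    for fid in block.feature_ids:
        m = meta.get(fid)
        if m is None or m.mz is None or m.rt is None:
            logger.debug("feature %s lacks mz/rt; left as isolated vertex", fid)
            continue
        feats.append((fid, m.mz, m.rt))
    feats.sort(key=lambda t: t[1])
    return feats


def build_satellite_graph(
    block: OmicsBlock,
    meta: FeatureMetaMap,
    params: RedundancyParams | None = None,
    rules: tuple[DeltaRule, ...] = DEFAULT_RULES,
) -> list[SatelliteEdge]:
    """Edges between co-eluting, correlated features at a known delta m/z.

    For a pair with mz_lo < mz_hi the offset ``mz_hi - mz_lo`` is matched
    against the rule table: isotope/adduct rules make the heavier feature
    the satellite, neutral-loss rules make the lighter one the satellite
    (fragment of the heavier parent).
    """
    params = params or RedundancyParams()
    feats = _ms_features(block, meta)
    values = {fid: block.data.loc[fid].to_numpy(dtype=float) for fid, _, _ in feats}
    max_delta = max(abs(r.delta_mz) for r in rules) + params.mz_tol

    edges: list[SatelliteEdge] = []
    for i, (fid_a, mz_a, rt_a) in enumerate(feats):
        for fid_b, mz_b, rt_b in feats[i + 1 :]:
            delta = mz_b - mz_a
            if delta > max_delta:
                break  # features sorted by mz
            if abs(rt_a - rt_b) > params.rt_tol:
                continue
            matched = None
            for rule in rules:
                if abs(delta - abs(rule.delta_mz)) <= params.mz_tol:
                    matched = rule
                    break
            if matched is None:
                continue
            rho = _spearman_rho(values[fid_a], values[fid_b])
            if not (rho >= params.corr_min):
                continue
            if matched.delta_mz >= 0:
                parent, satellite = fid_a, fid_b
            else:  # neutral loss: lighter feature is the in-source fragment
                parent, satellite = fid_b, fid_a
            edges.append(SatelliteEdge(parent, satellite, matched.name, matched.kind, rho))
    return edges


@dataclass
class CollapseReport:
    """Cluster membership, satellite roles and the collapsed matrix."""

    clusters: pd.DataFrame  # cluster_id, representative, member, role, rule
    collapsed: OmicsBlock
    edges: list[SatelliteEdge]

    @property
    def representatives(self) -> list[str]:
        return list(dict.fromkeys(self.clusters["representative"]))


def collapse_clusters(
    edges: list[SatelliteEdge], block: OmicsBlock
) -> CollapseReport:
    """Connected components -> one representative feature per cluster.

    The representative is the member with the highest mean abundance among
    those never assigned an isotope or fragment role (falling back to the
    overall highest mean); ties break on feature id for determinism.
    """
    graph = nx.Graph()
    graph.add_nodes_from(block.feature_ids)
    roles: dict[str, set[str]] = {fid: set() for fid in block.feature_ids}
    rule_of: dict[str, str] = {}
    for e in edges:
        graph.add_edge(e.parent, e.satellite)
        roles[e.satellite].add(e.kind)
        rule_of.setdefault(e.satellite, e.rule)

    mean_abund = block.data.mean(axis=1)
    rows = []
    rep_order: list[str] = []
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    for cid, members in enumerate(components):
        def rank(fid: str):
            return (-float(mean_abund.get(fid, -np.inf)), fid)

        eligible = [
            f for f in members if not roles[f] & {KIND_ISOTOPE, KIND_FRAGMENT}
        ]
        pool = eligible or members
        representative = min(pool, key=rank)
        rep_order.append(representative)
        for member in members:
            role = "parent" if member == representative else (
                "/".join(sorted(roles[member])) or "correlated"
            )
            rows.append(
                {
                    "cluster_id": cid,
                    "representative": representative,
                    "member": member,
                    "role": role,
                    "rule": rule_of.get(member, ""),
                }
            )
    collapsed = OmicsBlock(block.name, block.data.loc[rep_order].copy())
    return CollapseReport(pd.DataFrame(rows), collapsed, edges)


def collapse_block(
    block: OmicsBlock,
    meta: FeatureMetaMap,
    params: RedundancyParams | None = None,
    rules: tuple[DeltaRule, ...] = DEFAULT_RULES,
) -> CollapseReport:
    """Convenience: build the satellite graph and collapse it."""
    return collapse_clusters(build_satellite_graph(block, meta, params, rules), block)


def flag_peptides(
    block: OmicsBlock, meta: FeatureMetaMap, params: RedundancyParams | None = None
) -> set[str]:
    """Features showing a doubly-charged isotope partner (~0.5017 Th).

    A co-eluting, correlated pair at the z=2 isotope spacing indicates a
    multiply-charged (peptide-like) ion; both members are flagged and
    should be excluded from metabolite-level stable sets.
    """
    params = params or RedundancyParams()
    feats = _ms_features(block, meta)
    values = {fid: block.data.loc[fid].to_numpy(dtype=float) for fid, _, _ in feats}
    flagged: set[str] = set()
    for i, (fid_a, mz_a, rt_a) in enumerate(feats):
        for fid_b, mz_b, rt_b in feats[i + 1 :]:
            delta = mz_b - mz_a
            if delta > params.isotope_spacing_z2 + params.mz_tol:
                break
            if abs(rt_a - rt_b) > params.rt_tol:
                continue
            if abs(delta - params.isotope_spacing_z2) > params.mz_tol:
                continue
            rho = _spearman_rho(values[fid_a], values[fid_b])
            if rho >= params.corr_min:
                flagged.update((fid_a, fid_b))
    return flagged
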