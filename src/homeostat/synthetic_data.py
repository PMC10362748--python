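"""Synthetic stage x truss multi-omics datasets with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* a 9-stage x 3-truss design with two missing cells (25 biological
  samples), plus pooled-QC and extraction-blank samples;
* lognormal abundances: ``exp(baseline + stage effect + truss effect +
  factor loadings x stage profile + noise)``;
* planted *stable* features whose stage and truss effects keep both
  expected CVs in the 10-15% band, against *varying* features whose
  between-stage CVs exceed 60%;
* three latent factors with smooth, mutually orthogonal stage profiles
  (early peak, mid peak, ramp-up) loading on a few stable metabolites
  and dedicated protein/transcript groups;
* LC-MS satellite features (isotopes, adducts, in-source fragments)
  co-eluting with and proportional to their parents, one doubly-charged
  peptide pair, blank contaminants and QC-unstable features;
* hierarchical functional categories with planted enrichment among
  factor members.

Everything is deterministic under a fixed seed, and a
:class:`GroundTruthManifest` records every planted structure so each
pipeline stage can be scored against the truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    FeatureMeta,
    FeatureMetaMap,
    OmicsBlock,
    PathwayMap,
    StudyDesign,
    write_annotation,
    write_pathways,
)
from .ms_redundancy import DEFAULT_RULES, DeltaRule, write_rules

STAGE_DPA = (8, 15, 21, 28, 34, 42, 48, 50, 53)
TRUSSES = ("T5", "T6", "T7")

#: satellite intensity relative to the parent ion
SATELLITE_RATIOS = {"isotope": 0.25, "adduct": 0.4, "fragment": 0.3}
_SAT_RULE = {"isotope": "isotope_13C", "adduct": "adduct_Na", "fragment": "loss_H2O"}
_SAT_DELTA = {"isotope": 1.00335, "adduct": 21.98194, "fragment": -18.01056}

TOP_BINS = ("1", "2", "3", "5", "7", "10", "11", "17", "19", "21")


@dataclass
class SimConfig:
    """Study conditions for the simulator; defaults are desk scale."""

    n_stages: int = 9
    n_trusses: int = 3
    n_missing_cells: int = 2
    block_sizes: dict = field(
        default_factory=lambda: {"metabolome": 300, "proteome": 1000, "transcriptome": 3000}
    )
    n_stable: dict = field(
        default_factory=lambda: {"metabolome": 22, "proteome": 40, "transcriptome": 40}
    )
    n_latent_factors: int = 3
    metabolites_per_factor: int = 7
    features_per_factor: dict = field(
        default_factory=lambda: {"proteome": [70, 69, 68], "transcriptome": [70, 69, 68]}
    )
    satellite_spec: dict = field(default_factory=lambda: {"isotope": 1, "adduct": 1})
    n_satellite_parents: int = 30
    n_peptides: int = 1
    n_contaminants: int = 5
    n_qc_unstable: int = 5
    n_qc: int = 3
    n_blank: int = 2
    enriched_categories: list = field(
        default_factory=lambda: [("7", 5.0), ("17", 5.0), ("21", 5.0)]
    )
    # log-scale effect sizes; factor amplitudes decrease across factors so
    # the cross-covariance singular values stay well separated (degenerate
    # factor strengths would let components rotate arbitrarily)
    noise_cv: float = 7.0  # percent; residual noise of stable features
    stable_stage_sd: float = 0.08
    stable_truss_sd: float = 0.07
    factor_amp_metabolite: tuple = (0.13, 0.12, 0.11)
    factor_amp_omics: tuple = (1.15, 0.95, 0.8)
    factor_noise_sd: float = 0.1
    varying_stage_sd: float = 0.1
    varying_noise_sd: float = 1.2
    satellite_jitter_sd: float = 0.02
    qc_noise_sd: float = 0.03
    stable_cv_budget: float = 20.0  # percent; analytic stable CV must stay below this
    seed: int = 0

    def __post_init__(self) -> None:
        for name, size in self.block_sizes.items():
            if size <= 0:
                raise ValueError(f"block size for {name} must be positive")
        if self.n_missing_cells > self.n_stages * (self.n_trusses - 2):
            raise ValueError("missing cells would leave a stage with <2 trusses")
        sigma_n = self.noise_cv / 100.0
        stage_sigma = math.sqrt(
            self.stable_stage_sd**2
            + (self.stable_truss_sd**2 + sigma_n**2) / self.n_trusses
        )
        expected_cv = 100.0 * math.sqrt(math.exp(stage_sigma**2) - 1.0)
        if expected_cv > self.stable_cv_budget:
            raise ValueError(
                f"infeasible config: expected stable between-stage CV "
                f"{expected_cv:.1f}% exceeds the {self.stable_cv_budget}% budget"
            )


def expected_stable_cvs(config: SimConfig) -> tuple[float, float]:
    """Analytic (between_stage, between_truss) CV expectations, percent."""
    sigma_n = config.noise_cv / 100.0
    stage_sigma = math.sqrt(
        config.stable_stage_sd**2
        + (config.stable_truss_sd**2 + sigma_n**2) / config.n_trusses
    )
    truss_sigma = math.sqrt(config.stable_truss_sd**2 + sigma_n**2)
    to_cv = lambda s: 100.0 * math.sqrt(math.exp(s**2) - 1.0)
    return to_cv(stage_sigma), to_cv(truss_sigma)


@dataclass
class GroundTruthManifest:
    """Everything planted: the key against which recovery is scored."""

    stable_ids: dict  # block -> list of feature ids
    factor_members: list  # per factor: block -> list of feature ids
    satellites: dict  # parent id -> list of {"id", "rule"}
    peptide_ids: list
    contaminant_ids: list
    qc_unstable_ids: list
    enriched_bins: list  # per factor, the 5x-enriched top-level BIN

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimResult:
    design: StudyDesign
    blocks: dict  # name -> OmicsBlock (includes QC/blank columns for metabolome)
    meta: FeatureMetaMap
    pathways: PathwayMap
    manifest: GroundTruthManifest
    weights: dict  # sample_id -> extraction mass (mg), metabolome
    rules: tuple[DeltaRule, ...] = DEFAULT_RULES


def _stage_profiles(n_stages: int, n_factors: int) -> np.ndarray:
    """Smooth orthonormal stage templates: early peak, mid peak, ramp-up."""
    t = np.linspace(0.0, 1.0, n_stages)
    raw = np.stack(
        [
            np.exp(-(((t - 0.08) / 0.22) ** 2)),
            np.exp(-(((t - 0.5) / 0.18) ** 2)),
            t,
        ]
    )[:n_factors]
    # Gram-Schmidt on centred templates, then unit sd per profile
    out = []
    for row in raw:
        v = row - row.mean()
        for prev in out:
            v = v - (v @ prev) / (prev @ prev) * prev
        out.append(v)
    profiles = np.stack([v / v.std(ddof=0) for v in out])
    return profiles


def _make_design(config: SimConfig, rng: np.random.Generator) -> StudyDesign:
    stages = STAGE_DPA[: config.n_stages]
    trusses = TRUSSES[: config.n_trusses]
    cells = [(s, t) for s in stages for t in trusses]
    # drop cells in distinct stages so every stage keeps >=2 trusses
    drop_stages = rng.choice(len(stages), size=config.n_missing_cells, replace=False)
    dropped = {
        (stages[si], trusses[rng.integers(len(trusses))]) for si in drop_stages
    }
    rows = []
    for stage, truss in cells:
        if (stage, truss) in dropped:
            continue
        rows.append(
            {"sample_id": f"S{stage:02d}{truss}", "stage_dpa": float(stage),
             "truss": truss, "role": "biological"}
        )
    for i in range(config.n_qc):
        rows.append({"sample_id": f"QC{i + 1}", "stage_dpa": np.nan, "truss": np.nan,
                     "role": "qc"})
    for i in range(config.n_blank):
        rows.append({"sample_id": f"BLK{i + 1}", "stage_dpa": np.nan, "truss": np.nan,
                     "role": "blank"})
    return StudyDesign(pd.DataFrame(rows).set_index("sample_id"))


def _assign_bins(
    rng: np.random.Generator,
    n: int,
    annotated_rate: float,
    boost_bin: str | None = None,
    fold: float = 1.0,
) -> list[tuple[bool, str | None]]:
    probs = np.ones(len(TOP_BINS)) / len(TOP_BINS)
    if boost_bin is not None:
        probs[TOP_BINS.index(boost_bin)] *= fold
        probs /= probs.sum()
    out = []
    for _ in range(n):
        if rng.random() < annotated_rate:
            top = TOP_BINS[rng.choice(len(TOP_BINS), p=probs)]
            path = f"{top}.{rng.integers(1, 10)}.{rng.integers(1, 10)}"
            out.append((True, path))
        else:
            out.append((False, None))
    return out


def _bio_log_matrix(
    rng: np.random.Generator,
    config: SimConfig,
    stage_idx: np.ndarray,
    truss_idx: np.ndarray,
    classes: list[str],
    factor_of: dict[int, int],
    profiles: np.ndarray,
    amp_factor: tuple,
    factor_noise_sd: float,
) -> np.ndarray:
    """Log-scale biological values for one block, one row per feature."""
    n_feat = len(classes)
    n_bio = stage_idx.size
    n_stages = profiles.shape[1] if profiles.size else config.n_stages
    baseline = rng.normal(np.log(1000.0), 1.0, size=n_feat)
    truss_eff = rng.normal(0.0, config.stable_truss_sd, size=(n_feat, config.n_trusses))
    log_vals = np.empty((n_feat, n_bio))
    sigma_n = config.noise_cv / 100.0
    for i, cls in enumerate(classes):
        if i in factor_of:
            f = factor_of[i]
            stage_eff = amp_factor[f] * profiles[f]
            noise_sd = factor_noise_sd if cls == "factor" else sigma_n
        elif cls == "stable":
            stage_eff = rng.normal(0.0, config.stable_stage_sd, size=n_stages)
            noise_sd = sigma_n
        else:  # varying
            stage_eff = rng.normal(0.0, config.varying_stage_sd, size=n_stages)
            noise_sd = config.varying_noise_sd
        log_vals[i] = (
            baseline[i]
            + stage_eff[stage_idx]
            + truss_eff[i, truss_idx]
            + rng.normal(0.0, noise_sd, size=n_bio)
        )
    return log_vals


def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate design, omics blocks, metadata, pathways and the manifest."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    design = _make_design(config, rng)
    bio = design.biological_samples
    stage_list = design.stages
    stage_idx = np.array(
        [stage_list.index(design.table.loc[s, "stage_dpa"]) for s in bio]
    )
    truss_list = design.trusses
    truss_idx = np.array([truss_list.index(design.table.loc[s, "truss"]) for s in bio])
    profiles = _stage_profiles(config.n_stages, config.n_latent_factors)

    meta: FeatureMetaMap = {}
    manifest_factors = [
        {"metabolome": [], "proteome": [], "transcriptome": []}
        for _ in range(config.n_latent_factors)
    ]
    enriched_bins = [b for b, _f in config.enriched_categories][: config.n_latent_factors]

    blocks: dict[str, OmicsBlock] = {}
    stable_ids: dict[str, list[str]] = {}

    # ---------------- proteome & transcriptome ----------------
    for bname, prefix, ann_rate in (("proteome", "P", 0.6), ("transcriptome", "T", 0.4)):
        size = config.block_sizes[bname]
        n_stab = config.n_stable[bname]
        fac_sizes = list(config.features_per_factor[bname])[: config.n_latent_factors]
        n_factor_total = sum(fac_sizes)
        n_vary = size - n_stab - n_factor_total
        if n_vary < 0:
            raise ValueError(f"{bname}: stable + factor features exceed block size")
        ids = [f"{prefix}{i + 1:05d}" for i in range(size)]
        classes = ["stable"] * n_stab + ["factor"] * n_factor_total + ["varying"] * n_vary
        factor_of = {}
        offset = n_stab
        for f, fac_size in enumerate(fac_sizes):
            for j in range(fac_size):
                factor_of[offset + j] = f
            offset += fac_size
        log_vals = _bio_log_matrix(
            rng, config, stage_idx, truss_idx, classes, factor_of, profiles,
            tuple(config.factor_amp_omics), config.factor_noise_sd,
        )
        blocks[bname] = OmicsBlock(
            bname, pd.DataFrame(np.exp(log_vals), index=ids, columns=bio)
        )
        stable_ids[bname] = ids[:n_stab]
        for idx, f in factor_of.items():
            manifest_factors[f][bname].append(ids[idx])
        # categories: planted enrichment inside each factor's member set
        bins = _assign_bins(rng, n_stab + n_vary, ann_rate)
        plain_iter = iter(bins)
        for i, fid in enumerate(ids):
            if i in factor_of:
                ann, path = _assign_bins(
                    rng, 1, 0.8, enriched_bins[factor_of[i]],
                    dict(config.enriched_categories).get(enriched_bins[factor_of[i]], 5.0),
                )[0]
            else:
                ann, path = next(plain_iter)
            platform = "protein" if bname == "proteome" else "transcript"
            meta[fid] = FeatureMeta(fid, platform, path, ann)

    # ---------------- metabolome ----------------
    size = config.block_sizes["metabolome"]
    n_stab = config.n_stable["metabolome"]
    n_fac_met = config.metabolites_per_factor * config.n_latent_factors
    if n_fac_met > n_stab:
        raise ValueError("factor metabolites must fit within the stable set")
    sat_per_parent = sum(config.satellite_spec.values())
    n_sat = config.n_satellite_parents * sat_per_parent
    n_pep = 2 * config.n_peptides
    n_core = size - n_sat - n_pep - config.n_contaminants
    n_vary = n_core - n_stab
    if n_vary < config.n_satellite_parents:
        raise ValueError("metabolome block too small for the requested structure")

    met_ids = [f"M{i + 1:04d}" for i in range(n_core)]
    classes = ["stable"] * n_stab + ["varying"] * n_vary
    factor_of = {
        f * config.metabolites_per_factor + j: f
        for f in range(config.n_latent_factors)
        for j in range(config.metabolites_per_factor)
    }
    log_vals = _bio_log_matrix(
        rng, config, stage_idx, truss_idx, classes, factor_of, profiles,
        tuple(config.factor_amp_metabolite), config.noise_cv / 100.0,
    )
    nat = np.exp(log_vals)
    stable_ids["metabolome"] = met_ids[:n_stab]
    for idx, f in factor_of.items():
        manifest_factors[f]["metabolome"].append(met_ids[idx])

    # platforms: stable set mixes NMR, targeted LC-MS and untargeted LC-MS;
    # everything varying is untargeted LC-MS
    platform_of: dict[str, str] = {}
    for i, fid in enumerate(met_ids):
        if i < 8:
            platform_of[fid] = "NMR"
        elif i < 10:
            platform_of[fid] = "LCMS_targeted"
        else:
            platform_of[fid] = "LCMS_untargeted"

    mz = dict(zip(met_ids, rng.uniform(150.0, 900.0, size=len(met_ids))))
    rt = dict(zip(met_ids, rng.uniform(60.0, 1200.0, size=len(met_ids))))

    # satellite parents: every stable untargeted feature plus the first
    # varying ones, up to n_satellite_parents
    stable_lcms = [f for f in met_ids[:n_stab] if platform_of[f] == "LCMS_untargeted"]
    varying_lcms = [f for f in met_ids[n_stab:]]
    parents = (stable_lcms + varying_lcms)[: config.n_satellite_parents]

    rows = {fid: nat[i] for i, fid in enumerate(met_ids)}
    satellites: dict[str, list[dict]] = {}
    for parent in parents:
        satellites[parent] = []
        for kind, count in config.satellite_spec.items():
            for j in range(count):
                sid = f"{parent}_{kind}{j + 1}"
                jitter = np.exp(
                    rng.normal(0.0, config.satellite_jitter_sd, size=len(bio))
                )
                rows[sid] = rows[parent] * SATELLITE_RATIOS[kind] * jitter
                mz[sid] = mz[parent] + _SAT_DELTA[kind] + rng.uniform(-0.003, 0.003)
                rt[sid] = rt[parent] + rng.uniform(-1.0, 1.0)
                platform_of[sid] = "LCMS_untargeted"
                satellites[parent].append({"id": sid, "rule": _SAT_RULE[kind]})

    # one doubly-charged (peptide-like) pair with stable-looking CVs
    peptide_ids: list[str] = []
    for k in range(config.n_peptides):
        a, b = f"PEP{k + 1}a", f"PEP{k + 1}b"
        base = (
            rng.normal(np.log(2000.0), 0.3)
            + rng.normal(0.0, config.stable_stage_sd, size=config.n_stages)[stage_idx]
            + rng.normal(0.0, config.stable_truss_sd, size=config.n_trusses)[truss_idx]
            + rng.normal(0.0, config.noise_cv / 100.0, size=len(bio))
        )
        rows[a] = np.exp(base)
        rows[b] = rows[a] * 0.55 * np.exp(
            rng.normal(0.0, config.satellite_jitter_sd, size=len(bio))
        )
        mz[a] = rng.uniform(400.0, 700.0)
        mz[b] = mz[a] + 0.5017 + rng.uniform(-0.002, 0.002)
        rt[a] = rng.uniform(60.0, 1200.0)
        rt[b] = rt[a] + rng.uniform(-0.5, 0.5)
        platform_of[a] = platform_of[b] = "LCMS_untargeted"
        peptide_ids += [a, b]

    # blank contaminants: as abundant in blanks as in biological samples
    contaminant_ids = [f"CONT{i + 1}" for i in range(config.n_contaminants)]
    for fid in contaminant_ids:
        level = rng.normal(np.log(5000.0), 0.3)
        rows[fid] = np.exp(level + rng.normal(0.0, 0.8, size=len(bio)))
        mz[fid] = rng.uniform(150.0, 900.0)
        rt[fid] = rng.uniform(60.0, 1200.0)
        platform_of[fid] = "LCMS_untargeted"

    all_met_ids = list(rows)
    bio_mat = np.vstack([rows[f] for f in all_met_ids])

    # QC samples: pooled profile + small injection noise; a few features get
    # a deliberately unstable QC response (picked clear of satellite parents)
    first_free = n_stab + max(0, config.n_satellite_parents - len(stable_lcms))
    qc_unstable_ids = met_ids[first_free : first_free + config.n_qc_unstable]
    qc_ids = design.qc_samples
    log_mean = np.log(bio_mat).mean(axis=1, keepdims=True)
    qc_noise = np.full((len(all_met_ids), 1), config.qc_noise_sd)
    unstable_rows = [all_met_ids.index(f) for f in qc_unstable_ids]
    qc_noise[unstable_rows] = 0.8
    qc_mat = np.exp(
        log_mean + rng.normal(0.0, 1.0, size=(len(all_met_ids), len(qc_ids))) * qc_noise
    )

    # blanks: near-zero except contaminants
    blank_ids = design.blank_samples
    blank_mat = np.exp(
        np.log(bio_mat).mean(axis=1, keepdims=True)
        - 6.0
        + rng.normal(0.0, 0.3, size=(len(all_met_ids), len(blank_ids)))
    )
    cont_rows = [all_met_ids.index(f) for f in contaminant_ids]
    blank_mat[cont_rows] = np.exp(
        np.log(bio_mat[cont_rows]).mean(axis=1, keepdims=True)
        + rng.normal(0.0, 0.2, size=(len(cont_rows), len(blank_ids)))
    )

    # extraction-weight nuisance, removed later by weight normalization
    weights = {
        s: float(w)
        for s, w in zip(
            bio + qc_ids + blank_ids,
            np.round(rng.uniform(18.0, 22.0, size=len(bio) + len(qc_ids) + len(blank_ids)), 2),
        )
    }
    full = np.hstack([bio_mat, qc_mat, blank_mat])
    cols = bio + qc_ids + blank_ids
    scale = np.array([weights[s] / 20.0 for s in cols])
    blocks["metabolome"] = OmicsBlock(
        "metabolome", pd.DataFrame(full * scale, index=all_met_ids, columns=cols)
    )

    for fid in all_met_ids:
        platform = platform_of[fid]
        is_lcms = platform == "LCMS_untargeted"
        annotated = platform in ("NMR", "LCMS_targeted", "enzymatic")
        meta[fid] = FeatureMeta(
            fid,
            platform,
            f"3.{rng.integers(1, 10)}" if annotated else None,
            annotated,
            mz=float(mz[fid]) if is_lcms else None,
            rt=float(rt[fid]) if is_lcms else None,
        )

    # pathway map: factor metabolites point at a few same-factor members
    # (signal) plus random varying features (null)
    pathways: PathwayMap = {}
    vary_prot = [f for f in blocks["proteome"].feature_ids if f not in
                 set(stable_ids["proteome"])][-200:]
    vary_tran = [f for f in blocks["transcriptome"].feature_ids if f not in
                 set(stable_ids["transcriptome"])][-200:]
    for f in range(config.n_latent_factors):
        if not manifest_factors[f]["metabolome"]:
            continue
        met = manifest_factors[f]["metabolome"][0]
        members = (
            manifest_factors[f]["proteome"][:5]
            + manifest_factors[f]["transcriptome"][:5]
            + list(rng.choice(vary_prot, size=5, replace=False))
            + list(rng.choice(vary_tran, size=5, replace=False))
        )
        pathways[met] = members

    manifest = GroundTruthManifest(
        stable_ids=stable_ids,
        factor_members=manifest_factors,
        satellites=satellites,
        peptide_ids=peptide_ids,
        contaminant_ids=contaminant_ids,
        qc_unstable_ids=qc_unstable_ids,
        enriched_bins=enriched_bins,
    )
    return SimResult(design, blocks, meta, pathways, manifest, weights)


def write_fixture(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write every external-interface file; byte-reproducible per seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["design"] = out / "design.tsv"
    result.design.write(paths["design"])
    for name, block in result.blocks.items():
        paths[name] = out / f"{name}.tsv"
        block.write(paths[name])
    paths["annotation"] = out / "annotation.tsv"
    write_annotation(result.meta, paths["annotation"])
    paths["pathways"] = out / "pathways.tsv"
    write_pathways(result.pathways, paths["pathways"])
    paths["rules"] = out / "rules.tsv"
    write_rules(result.rules, paths["rules"])
    paths["weights"] = out / "weights.tsv"
    pd.DataFrame(
        sorted(result.weights.items()), columns=["sample_id", "weight_mg"]
    ).to_csv(paths["weights"], sep="\t", index=False)
    paths["manifest"] = out / "manifest.json"
    result.manifest.to_json(paths["manifest"])
    return paths
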