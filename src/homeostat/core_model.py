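"""Domain types and readers for stage x truss multi-omics studies.

The experimental design is a developmental time course (stages, measured in
days post-anthesis) crossed with replicate blocks (trusses, i.e. fruit
clusters on the plant).  Omics blocks are feature x sample abundance
matrices sharing that design.  Missing values are stored as missing (NaN),
never as zero, and are excluded pairwise downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLE_BIOLOGICAL = "biological"
ROLE_QC = "qc"
ROLE_BLANK = "blank"
_ROLES = (ROLE_BIOLOGICAL, ROLE_QC, ROLE_BLANK)

PLATFORMS = (
    "NMR",
    "LCMS_untargeted",
    "LCMS_targeted",
    "LCDAD",
    "enzymatic",
    "protein",
    "transcript",
)


def _detect_sep(path: str | Path) -> str:
    """Pick the delimiter (tab/comma/semicolon) that splits the header most."""
    with open(path) as fh:
        header = fh.readline()
    counts = {sep: header.count(sep) for sep in ("\t", ",", ";")}
    sep = max(counts, key=counts.get)
    if counts[sep] == 0:
        raise ValueError(f"{path}: could not detect a tab/comma/semicolon delimiter")
    return sep


@dataclass
class StudyDesign:
    """Sample -> (stage, truss, role) mapping.

    ``table`` is indexed by sample_id with columns ``stage_dpa`` (float,
    NaN for QC/blank samples), ``truss`` (label) and ``role`` (one of
    biological/qc/blank).  Row order defines the canonical sample order.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids in design: {dups}")
        missing = [c for c in ("stage_dpa", "truss", "role") if c not in self.table.columns]
        if "role" in missing:
            self.table = self.table.assign(role=ROLE_BIOLOGICAL)
            missing.remove("role")
        if missing:
            raise ValueError(f"design table lacks columns: {missing}")
        bad_roles = set(self.table["role"]) - set(_ROLES)
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        bio = self.table[self.table["role"] == ROLE_BIOLOGICAL]
        if bio["stage_dpa"].isna().any() or bio["truss"].isna().any():
            bad = bio.index[bio["stage_dpa"].isna() | bio["truss"].isna()].tolist()
            raise ValueError(f"biological samples lacking stage or truss: {bad}")

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.table.index[self.table["role"] == role])

    @property
    def biological_samples(self) -> list[str]:
        return self.samples_with_role(ROLE_BIOLOGICAL)

    @property
    def qc_samples(self) -> list[str]:
        return self.samples_with_role(ROLE_QC)

    @property
    def blank_samples(self) -> list[str]:
        return self.samples_with_role(ROLE_BLANK)

    @property
    def stages(self) -> list[float]:
        bio = self.table[self.table["role"] == ROLE_BIOLOGICAL]
        return sorted(bio["stage_dpa"].unique())

    @property
    def trusses(self) -> list[str]:
        bio = self.table[self.table["role"] == ROLE_BIOLOGICAL]
        return sorted(bio["truss"].unique())

    def stage_groups(self, samples: list[str] | None = None) -> dict[float, list[str]]:
        """Biological samples grouped by stage (optionally restricted)."""
        bio = self.table[self.table["role"] == ROLE_BIOLOGICAL]
        if samples is not None:
            keep = set(samples)
            bio = bio.loc[[s for s in bio.index if s in keep]]
        return {
            stage: list(sub.index)
            for stage, sub in bio.groupby("stage_dpa", sort=True)
        }

    @classmethod
    def read(cls, path: str | Path) -> "StudyDesign":
        sep = _detect_sep(path)
        df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "truss": str})
        if "sample_id" not in df.columns:
            raise ValueError(f"{path}: design file needs a sample_id column")
        df = df.set_index("sample_id")
        if "role" in df.columns:
            df["role"] = df["role"].fillna(ROLE_BIOLOGICAL)
        return cls(df)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class OmicsBlock:
    """One omics abundance matrix, features x samples, NaN = missing."""

    name: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"block {self.name!r}: duplicated feature ids {dups}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    def subset_samples(self, samples: list[str]) -> "OmicsBlock":
        return OmicsBlock(self.name, self.data.loc[:, samples].copy())

    def subset_features(self, features: list[str]) -> "OmicsBlock":
        return OmicsBlock(self.name, self.data.loc[features].copy())

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="feature_id", float_format="%.10g")


def read_block(path: str | Path, design: StudyDesign, name: str | None = None) -> OmicsBlock:
    """Read a delimited feature x sample matrix validated against the design.

    First column holds feature ids, header row holds sample ids.  Columns are
    reordered to the design's sample order; blank cells become missing values.
    Unknown sample ids and duplicated feature ids are hard errors.
    """
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    unknown = [s for s in df.columns if s not in design.table.index]
    if unknown:
        raise ValueError(f"{path}: sample ids not in design: {unknown}")
    order = [s for s in design.sample_ids if s in set(df.columns)]
    block = OmicsBlock(name or Path(path).stem, df.loc[:, order].astype(float))
    n_missing = int(block.data.isna().sum().sum())
    if n_missing:
        logger.info("block %s: %d missing entries recorded", block.name, n_missing)
    return block


def align_blocks(blocks: list[OmicsBlock], design: StudyDesign) -> list[OmicsBlock]:
    """Restrict all blocks to their shared biological samples, same order.

    Idempotent; raises if the intersection of biological samples is empty.
    """
    if not blocks:
        raise ValueError("align_blocks needs at least one block")
    shared = set(design.biological_samples)
    for block in blocks:
        shared &= set(block.sample_ids)
    if not shared:
        raise ValueError(
            "no biological sample shared by all blocks: "
            + ", ".join(b.name for b in blocks)
        )
    order = [s for s in design.sample_ids if s in shared]
    return [b.subset_samples(order) for b in blocks]


@dataclass
class FeatureMeta:
    """Per-feature metadata: platform, functional BIN, annotation, m/z, RT.

    ``bin_path`` is a dot-separated hierarchical category code (Mercator
    style, e.g. "3.9.1.2").  m/z (Th) and retention time (s) are present
    exactly for untargeted LC-MS features.
    """

    feature_id: str
    platform: str
    bin_path: str | None = None
    annotated: bool = False
    mz: float | None = None
    rt: float | None = None

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"{self.feature_id}: unknown platform {self.platform!r}")
        has_ms = self.mz is not None and self.rt is not None
        if (self.platform == "LCMS_untargeted") != has_ms:
            raise ValueError(
                f"{self.feature_id}: mz/rt must be present iff platform is "
                f"LCMS_untargeted (got platform={self.platform}, mz={self.mz}, rt={self.rt})"
            )

    def bin_prefix(self, depth: int = 1) -> str | None:
        if not self.bin_path:
            return None
        return ".".join(self.bin_path.split(".")[:depth])


FeatureMetaMap = dict[str, FeatureMeta]


def read_annotation(path: str | Path) -> FeatureMetaMap:
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"feature_id": str, "bin_path": str})
    metas: FeatureMetaMap = {}
    for row in df.itertuples(index=False):
        bin_path = getattr(row, "bin_path", None)
        if isinstance(bin_path, float) and np.isnan(bin_path):
            bin_path = None
        mz = getattr(row, "mz", np.nan)
        rt = getattr(row, "rt", np.nan)
        meta = FeatureMeta(
            feature_id=row.feature_id,
            platform=row.platform,
            bin_path=bin_path if bin_path else None,
            annotated=bool(int(row.annotated)),
            mz=None if pd.isna(mz) else float(mz),
            rt=None if pd.isna(rt) else float(rt),
        )
        if meta.feature_id in metas:
            raise ValueError(f"{path}: duplicated feature id {meta.feature_id}")
        metas[meta.feature_id] = meta
    return metas


def write_annotation(metas: FeatureMetaMap, path: str | Path) -> None:
    rows = [
        {
            "feature_id": m.feature_id,
            "platform": m.platform,
            "bin_path": m.bin_path or "",
            "annotated": int(m.annotated),
            "mz": "" if m.mz is None else f"{m.mz:.5f}",
            "rt": "" if m.rt is None else f"{m.rt:.2f}",
        }
        for m in metas.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


PathwayMap = dict[str, list[str]]


def read_pathways(path: str | Path) -> PathwayMap:
    """Two-column TSV (metabolite_id, member_id) -> metabolite -> members."""
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: pathway file needs two columns")
    met_col, mem_col = df.columns[:2]
    pathways: PathwayMap = {}
    for met, sub in df.groupby(met_col, sort=False):
        pathways[met] = list(sub[mem_col])
    return pathways


def write_pathways(pathways: PathwayMap, path: str | Path) -> None:
    rows = [
        {"metabolite_id": met, "member_id": member}
        for met, members in pathways.items()
        for member in members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
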