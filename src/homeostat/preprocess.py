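"""Untargeted LC-MS matrix filters applied before analysis.

Three optional, idempotent steps in documented order:

1. **blank filter** — drop features whose mean biological abundance is
   less than ``blank_ratio_min`` times their mean blank abundance
   (features silent in every blank always pass); blank columns are
   removed from the output.
2. **QC-CV filter** — drop features whose CV across pooled-QC injections
   exceeds ``qc_cv_max`` percent (strict >).
3. **weight normalization** — divide each sample column by its
   extraction mass (mg); CVs are invariant to this when masses are equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_model import OmicsBlock, StudyDesign
from .stability import cv

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    blank_ratio_min: float = 3.0  # biological/blank mean ratio below which a feature is dropped
    qc_cv_max: float = 50.0  # percent
    weights: dict[str, float] | None = None  # sample_id -> extraction mass (mg)

    def __post_init__(self) -> None:
        if self.blank_ratio_min <= 1:
            raise ValueError("blank_ratio_min must exceed 1")
        if self.qc_cv_max <= 0:
            raise ValueError("qc_cv_max must be positive")


def blank_filter(
    block: OmicsBlock, design: StudyDesign, params: PreprocessParams | None = None
) -> OmicsBlock:
    params = params or PreprocessParams()
    blanks = [s for s in design.blank_samples if s in block.data.columns]
    if not blanks:
        raise ValueError(
            "no blank samples present in the block; skip the blank filter instead"
        )
    bio = [s for s in design.biological_samples if s in block.data.columns]
    blank_mean = block.data[blanks].mean(axis=1)  # NaN when missing in all blanks
    bio_mean = block.data[bio].mean(axis=1)
    drop = (bio_mean < params.blank_ratio_min * blank_mean).fillna(False)
    if drop.any():
        logger.info("blank filter removed %d features", int(drop.sum()))
    keep_cols = [c for c in block.data.columns if c not in set(blanks)]
    return OmicsBlock(block.name, block.data.loc[~drop, keep_cols].copy())


def qc_cv_filter(
    block: OmicsBlock, design: StudyDesign, params: PreprocessParams | None = None
) -> OmicsBlock:
    params = params or PreprocessParams()
    qcs = [s for s in design.qc_samples if s in block.data.columns]
    if len(qcs) < 3:
        raise ValueError(f"QC-CV filter needs >=3 QC samples, found {len(qcs)}")
    qc_cvs = block.data[qcs].apply(lambda row: cv(row.to_numpy()), axis=1)
    drop = (qc_cvs > params.qc_cv_max).fillna(False)  # undefined CV -> keep
    if drop.any():
        logger.info("QC-CV filter removed %d features", int(drop.sum()))
    return OmicsBlock(block.name, block.data.loc[~drop].copy())


def weight_normalize(block: OmicsBlock, params: PreprocessParams) -> OmicsBlock:
    """Divide each sample column by its extraction mass."""
    weights = params.weights or {}
    data = block.data.copy()
    for sample in data.columns:
        w = weights.get(sample)
        if w is None:
            raise ValueError(f"no extraction weight for sample {sample!r}")
        if w <= 0:
            raise ValueError(f"non-positive extraction weight for sample {sample!r}")
        data[sample] = data[sample] / w
    return OmicsBlock(block.name, data)
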