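import numpy as np
import pandas as pd
import pytest

from homeostat.core_model import OmicsBlock, StudyDesign
from homeostat.pipeline import PipelineConfig, run_pipeline
from homeostat.preprocess import PreprocessParams
from homeostat.sparse_pls import SplsParams
from homeostat.synthetic_data import SimConfig, simulate


def make_design(stages, trusses, missing=(), qc=0, blank=0):
    """Build a stage x truss design in code; ``missing`` lists (stage, truss)."""
    rows = []
    for s in stages:
        for t in trusses:
            if (s, t) in missing:
                continue
            rows.append({"sample_id": f"S{s:02d}{t}", "stage_dpa": float(s),
                         "truss": t, "role": "biological"})
    for i in range(qc):
        rows.append({"sample_id": f"QC{i+1}", "stage_dpa": np.nan, "truss": np.nan,
                     "role": "qc"})
    for i in range(blank):
        rows.append({"sample_id": f"BLK{i+1}", "stage_dpa": np.nan, "truss": np.nan,
                     "role": "blank"})
    return StudyDesign(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def design_2x3():
    return make_design([8, 15], ["T5", "T6", "T7"])


@pytest.fixture
def design_9x3():
    return make_design(
        [8, 15, 21, 28, 34, 42, 48, 50, 53], ["T5", "T6", "T7"],
        missing=[(21, "T6"), (48, "T7")],
    )


def block_from(design, values, feature_ids, name="test"):
    return OmicsBlock(
        name, pd.DataFrame(values, index=feature_ids, columns=design.biological_samples)
    )


@pytest.fixture(scope="session")
def sim():
    return simulate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_result(sim):
    config = PipelineConfig(
        preprocess=PreprocessParams(weights=sim.weights),
        spls=SplsParams(ncomp=3),
    )
    return run_pipeline(sim.design, sim.blocks, sim.meta, sim.pathways, config)
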