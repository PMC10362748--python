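"""Hierarchical CVs, dual-threshold selection, category profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeostat.core_model import FeatureMeta
from homeostat.stability import (
    StabilityParams,
    StabilityResult,
    between_stage_cv,
    between_truss_cv,
    category_cv_profile,
    compute_stability,
    cv,
    select_stable,
)
from homeostat.synthetic_data import SimConfig, simulate

from conftest import block_from, make_design


# ---------------------------------------------------------------- cv core
@pytest.mark.parametrize(
    "values,expected",
    [
        ([10, 12, 14], 100 * 2 / 12),  # sd 2, mean 12
        ([5, 5, 5], 0.0),
        ([12, 20], 100 * np.std([12, 20], ddof=1) / 16),
    ],
)
def test_cv_known_values(values, expected):
    assert cv(values) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("values", [[0, 0, 0], [7], [], [-1, 1], [np.nan, 3]])
def test_cv_undefined_cases(values):
    """Non-positive mean or <2 present values flag the CV as undefined."""
    assert np.isnan(cv(values))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(0.1, 1e6), min_size=2, max_size=30),
    st.floats(1e-3, 1e3),
)
def test_cv_scale_invariant(values, scale):
    base = cv(values)
    scaled = cv([v * scale for v in values])
    if np.isnan(base):
        assert np.isnan(scaled)
    else:
        assert scaled == pytest.approx(base, rel=1e-9)


# ------------------------------------------------- stratified CV operations
def test_between_truss_cv_mean_of_stage_cvs(design_2x3):
    values = pd.Series([10, 12, 14, 20, 20, 20],
                       index=design_2x3.biological_samples)
    result, n_used = between_truss_cv(values, design_2x3)
    assert result == pytest.approx((100 * 2 / 12 + 0.0) / 2, rel=1e-12)
    assert n_used == 2


def test_between_stage_cv_on_stage_means(design_2x3):
    values = pd.Series([12, 12, 12, 20, 20, 20],
                       index=design_2x3.biological_samples)
    result, n_used = between_stage_cv(values, design_2x3)
    assert result == pytest.approx(100 * np.std([12, 20], ddof=1) / 16, rel=1e-12)
    assert n_used == 2


def test_constant_feature_has_zero_cvs(design_9x3):
    values = pd.Series(3.0, index=design_9x3.biological_samples)
    assert between_truss_cv(values, design_9x3)[0] == 0.0
    assert between_stage_cv(values, design_9x3)[0] == 0.0


def test_missing_stage_excluded_and_counted(design_2x3):
    values = pd.Series([10, 12, 14, np.nan, np.nan, np.nan],
                       index=design_2x3.biological_samples)
    result, n_used = between_truss_cv(values, design_2x3)
    assert result == pytest.approx(100 * 2 / 12, rel=1e-12)
    assert n_used == 1
    # a single usable stage cannot give a between-stage CV
    assert np.isnan(between_stage_cv(values, design_2x3)[0])


def test_complete_grid_uses_all_nine_stages(design_9x3):
    """On a full grid the between-truss CV averages exactly one CV per stage."""
    design = make_design([8, 15, 21, 28, 34, 42, 48, 50, 53], ["T5", "T6", "T7"])
    rng = np.random.default_rng(5)
    values = pd.Series(rng.lognormal(3, 0.4, 27), index=design.biological_samples)
    _, n_used = between_truss_cv(values, design)
    assert n_used == 9


def brute_force_cvs(values: pd.Series, design):
    """Nested-loop oracle for both CV strata."""
    table = design.table
    per_stage, means = [], []
    for stage in sorted({table.loc[s, "stage_dpa"] for s in values.index
                         if table.loc[s, "role"] == "biological"}):
        vals = [values[s] for s in values.index
                if table.loc[s, "role"] == "biological"
                and table.loc[s, "stage_dpa"] == stage and not np.isnan(values[s])]
        if len(vals) >= 1:
            means.append(float(np.mean(vals)))
        if len(vals) >= 2 and np.mean(vals) > 0:
            per_stage.append(100 * np.std(vals, ddof=1) / np.mean(vals))
    ct = float(np.mean(per_stage)) if per_stage else np.nan
    if len(means) >= 2 and np.mean(means) > 0:
        cs = 100 * np.std(means, ddof=1) / np.mean(means)
    else:
        cs = np.nan
    return ct, cs


def test_vectorized_cvs_match_bruteforce_oracle(design_9x3):
    rng = np.random.default_rng(11)
    bio = design_9x3.biological_samples
    values = rng.lognormal(3, 0.6, size=(200, len(bio)))
    values[rng.random(values.shape) < 0.05] = np.nan  # scattered missing cells
    block = block_from(design_9x3, values, [f"f{i}" for i in range(200)])
    table = compute_stability(block, design_9x3).table
    for fid in block.feature_ids:
        ct, cs = brute_force_cvs(block.data.loc[fid], design_9x3)
        for got, want in ((table.loc[fid, "cv_truss"], ct), (table.loc[fid, "cv_stage"], cs)):
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, rel=1e-12)


# ------------------------------------------------------------- selection
def test_selection_boundary_is_strict(design_9x3):
    table = pd.DataFrame(
        {"cv_truss": [24.9, 25.0, 10.0], "cv_stage": [24.9, 10.0, np.nan]},
        index=["ok", "edge", "undef"],
    )
    # drive the real selection through synthetic values is overkill here;
    # exercise the rule through compute_stability on constructed data instead
    rng = np.random.default_rng(0)
    bio = design_9x3.biological_samples
    block = block_from(design_9x3, rng.lognormal(3, 0.05, size=(3, len(bio))),
                       ["a", "b", "c"])
    params = StabilityParams(cv_truss_max=25, cv_stage_max=25, strict=True)
    result = compute_stability(block, design_9x3, params)
    got = result.table
    for fid in got.index:  # tiny noise: everything far below threshold
        assert got.loc[fid, "selected"]
    # threshold exactly at the realized CV de-selects under strict comparison
    tight = StabilityParams(
        cv_truss_max=float(got["cv_truss"].iloc[0]),
        cv_stage_max=25.0,
        strict=True,
    )
    assert not compute_stability(block, design_9x3, tight).table["selected"].iloc[0]
    loose = StabilityParams(
        cv_truss_max=float(got["cv_truss"].iloc[0]),
        cv_stage_max=25.0,
        strict=False,
    )
    assert compute_stability(block, design_9x3, loose).table["selected"].iloc[0]


def test_raising_thresholds_never_removes_features(design_9x3):
    rng = np.random.default_rng(21)
    bio = design_9x3.biological_samples
    block = block_from(design_9x3, rng.lognormal(3, 0.3, size=(100, len(bio))),
                       [f"f{i}" for i in range(100)])
    small = set(compute_stability(block, design_9x3,
                                  StabilityParams(15, 15)).selected_ids)
    large = set(compute_stability(block, design_9x3,
                                  StabilityParams(30, 30)).selected_ids)
    assert small <= large


def test_planted_stable_recovery_across_seeds():
    """Planted stable vs varying features separate perfectly across 20 seeds."""
    config_kwargs = dict(
        block_sizes={"metabolome": 200, "proteome": 30, "transcriptome": 30},
        n_stable={"metabolome": 20, "proteome": 5, "transcriptome": 5},
        metabolites_per_factor=2,
        features_per_factor={"proteome": [3, 3, 3], "transcriptome": [3, 3, 3]},
        satellite_spec={},
        n_satellite_parents=0,
        n_peptides=0,
        n_contaminants=0,
        n_qc_unstable=0,
    )
    for seed in range(20):
        sim = simulate(SimConfig(seed=seed, **config_kwargs))
        block = sim.blocks["metabolome"]
        bio = sim.design.biological_samples
        block = block.subset_samples([s for s in bio if s in set(block.sample_ids)])
        selected = set(select_stable(block, sim.design).selected_ids)
        assert selected == set(sim.manifest.stable_ids["metabolome"]), f"seed {seed}"


# ------------------------------------------------------ category profiles
def make_result(cv_pairs):
    table = pd.DataFrame(
        {"cv_truss": [a for a, _ in cv_pairs.values()],
         "cv_stage": [b for _, b in cv_pairs.values()],
         "n_stages_used": 9, "selected": False},
        index=list(cv_pairs),
    )
    return StabilityResult(table, StabilityParams())


def metas_for(bins):
    return {fid: FeatureMeta(fid, "protein", b, True) for fid, b in bins.items()}


def test_category_profile_exact_wilcoxon():
    """Clearly separated CV distributions give the exact rank-sum p-value."""
    cvs = {f"a{i}": (v, v) for i, v in enumerate([5, 6, 7, 8])}
    cvs |= {f"b{i}": (v, v) for i, v in enumerate([50, 60, 70, 80])}
    result = make_result(cvs)
    meta = metas_for({f: ("1.1" if f.startswith("a") else "2.9") for f in cvs})
    profile = category_cv_profile(result, meta, level=1, min_members=3)
    assert profile.categories.loc["1", "mean_cv_truss"] == pytest.approx(6.5)
    assert profile.categories.loc["2", "mean_cv_truss"] == pytest.approx(65.0)
    truss_rows = profile.pairwise[profile.pairwise["metric"] == "cv_truss"]
    assert len(truss_rows) == 1
    assert truss_rows["p"].iloc[0] == pytest.approx(2 / 70, rel=1e-9)


def test_category_profile_identical_distributions_not_significant():
    cvs = {f"a{i}": (v, v) for i, v in enumerate([5, 6, 7, 8])}
    cvs |= {f"b{i}": (v, v) for i, v in enumerate([5, 6, 7, 8])}
    result = make_result(cvs)
    meta = metas_for({f: ("1.1" if f.startswith("a") else "2.9") for f in cvs})
    profile = category_cv_profile(result, meta, min_members=3, alpha=0.01)
    assert not profile.pairwise["significant"].any()
    assert (profile.pairwise["q"] > 0.5).all()


def test_category_profile_pair_count_and_min_size():
    cvs = {f"a{i}": (5.0 + i, 5.0 + i) for i in range(4)}
    cvs |= {f"b{i}": (15.0 + i, 15.0 + i) for i in range(4)}
    cvs |= {f"c{i}": (30.0 + i, 30.0 + i) for i in range(4)}
    cvs |= {"tiny1": (1.0, 1.0), "tiny2": (1.0, 1.0)}  # below min size -> excluded
    bins = {f: f"{ {'a':'1','b':'2','c':'3','t':'4'}[f[0]] }.5" for f in cvs}
    profile = category_cv_profile(make_result(cvs), metas_for(bins), min_members=3)
    assert set(profile.categories.index) == {"1", "2", "3"}
    per_metric = profile.pairwise.groupby("metric").size()
    assert (per_metric == 3).all()  # 3 categories -> 3 pairwise tests
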