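"""Spearman screens: scalar oracle, vectorization, pathway listings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from homeostat.association import (
    ScreenParams,
    pathway_correlations,
    screen_metabolite,
    spearman,
    spearman_screen,
)
from homeostat.core_model import FeatureMeta, OmicsBlock


def rank_pearson(x, y):
    """Brute-force oracle: average-rank transform then Pearson."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


def test_hand_worked_rank_correlation():
    rho, _p = spearman([1, 2, 3, 4], [3, 1, 2, 4])
    assert rho == pytest.approx(rank_pearson([1, 2, 3, 4], [3, 1, 2, 4]), abs=1e-12)
    # classic 3-point example extended to meet the minimum sample size
    assert spearman([1, 2, 3, 5], [3, 1, 2, 5])[0] == pytest.approx(
        rank_pearson([1, 2, 3, 5], [3, 1, 2, 5]), abs=1e-12)


def test_ties_use_average_ranks():
    rho, _ = spearman([1, 2, 2, 4], [1, 3, 3, 8])
    assert rho == pytest.approx(1.0)


def test_monotone_transform_invariance():
    x = np.linspace(1, 3, 12)
    y = np.exp(x)
    assert spearman(x, y)[0] == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    a = rng.normal(size=20)
    b = rng.normal(size=20)
    r1, p1 = spearman(a, b)
    r2, p2 = spearman(np.exp(a), b**3)
    assert r1 == pytest.approx(r2, abs=1e-12)
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_undefined_inputs_give_nan():
    assert np.isnan(spearman([1, 2, 3], [1, 2, 3])[0])  # <4 shared samples
    assert np.isnan(spearman([2, 2, 2, 2, 2], [1, 2, 3, 4, 5])[0])  # constant
    x = [1, 2, np.nan, np.nan, np.nan, 6]
    assert np.isnan(spearman(x, [1, 2, 3, 4, 5, 6])[0])


def test_scalar_matches_bruteforce_on_random_vectors_with_ties():
    rng = np.random.default_rng(1)
    for _ in range(300):
        n = rng.integers(5, 30)
        x = rng.integers(0, 8, size=n).astype(float)  # heavy ties
        y = rng.normal(size=n).round(1)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(rank_pearson(x, y), abs=1e-12)


def test_vectorized_screen_matches_scalar_path():
    rng = np.random.default_rng(2)
    y = rng.normal(size=25)
    X = rng.normal(size=(50, 25))
    X[3, 4] = np.nan  # forces the pairwise-complete fallback on one row
    rho_v, p_v = spearman_screen(y, X)
    for i in range(50):
        rho_s, p_s = spearman(y, X[i])
        assert rho_v[i] == pytest.approx(rho_s, abs=1e-12)
        assert p_v[i] == pytest.approx(p_s, abs=1e-10)


def test_small_sample_p_close_to_exact_permutation():
    """The t approximation tracks the exact permutation p-value at n<=9."""
    from itertools import permutations

    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0, 7.0])
    rho, p_t = spearman(x, y)
    null = [rank_pearson(x, np.array(perm)) for perm in permutations(y)]
    p_exact = np.mean(np.abs(null) >= abs(rho) - 1e-12)
    assert p_t == pytest.approx(p_exact, abs=0.02)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.integers(0, 10_000))
def test_screen_hits_invariant_under_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    y = pd.Series(rng.normal(size=12), index=[f"s{i}" for i in range(12)])
    X = rng.normal(size=(20, 12))
    block = OmicsBlock("b", pd.DataFrame(X, index=[f"f{i}" for i in range(20)],
                                         columns=y.index))
    block2 = OmicsBlock("b", np.exp(block.data))
    meta = {f: FeatureMeta(f, "protein", "1.1", True) for f in block.feature_ids}
    params = ScreenParams(alpha_unfocused=0.05)
    rec1, _ = screen_metabolite("m", y, block, meta, params)
    rec2, _ = screen_metabolite("m", np.exp(y), block2, meta, params)
    assert list(rec1["target_id"]) == list(rec2["target_id"])


def make_block_meta(rng, n_feat, y, signal_idx=(), rho_target=0.9, annotated_rate=1.0):
    n = y.size
    lam = rho_target / np.sqrt(1 - rho_target**2)
    X = rng.normal(size=(n_feat, n))
    for i in signal_idx:
        X[i] = lam * y + rng.normal(size=n)
    ids = [f"f{i}" for i in range(n_feat)]
    block = OmicsBlock("proteome", pd.DataFrame(X, index=ids,
                                                columns=[f"s{j}" for j in range(n)]))
    meta = {
        f: FeatureMeta(f, "protein", f"{(i % 9) + 1}.2", rng.random() < annotated_rate)
        for i, f in enumerate(ids)
    }
    return block, meta


def test_screen_recovers_planted_targets():
    """Planted rho~0.9 associations at n=25 survive the 1e-4 threshold."""
    rng = np.random.default_rng(3)
    y_vals = rng.normal(size=25)
    block, meta = make_block_meta(rng, 200, y_vals, signal_idx=range(40))
    y = pd.Series(y_vals, index=block.sample_ids)
    records, summary = screen_metabolite("m", y, block, meta)
    hits = set(records["target_id"])
    planted = {f"f{i}" for i in range(40)}
    assert len(hits & planted) >= 0.9 * len(planted)
    assert summary.reportable


def test_null_block_rarely_passes_stringent_threshold():
    rng = np.random.default_rng(4)
    for _ in range(20):
        y_vals = rng.normal(size=25)
        block, meta = make_block_meta(rng, 1000, y_vals)
        y = pd.Series(y_vals, index=block.sample_ids)
        records, _ = screen_metabolite("m", y, block, meta)
        # expectation per screen is 1000 x 1e-4 = 0.1 false positives
        assert len(records) <= 2


def test_reportability_needs_min_assigned():
    rng = np.random.default_rng(5)
    y_vals = rng.normal(size=25)
    block, meta = make_block_meta(rng, 60, y_vals, signal_idx=range(9))
    y = pd.Series(y_vals, index=block.sample_ids)
    _, summary = screen_metabolite("m", y, block, meta)
    assert summary.n_assigned <= 9
    assert not summary.reportable


def test_pathway_listing_small_membership_and_pfilter():
    rng = np.random.default_rng(6)
    y_vals = rng.normal(size=25)
    block, meta = make_block_meta(rng, 30, y_vals, signal_idx=(0, 1), rho_target=0.8)
    y = pd.Series(y_vals, index=block.sample_ids)
    members = ["f0", "f1", "f2", "ghost"]
    ranked, filtered = pathway_correlations("m", y, members, [block], meta)
    assert len(ranked) == 3  # fewer than top_k: all ranked; ghost unresolved
    assert set(filtered["target_id"]) == {"f0", "f1"}  # rho~0.8 -> p ~ 2e-6 at n=25


def test_pathway_constant_member_excluded():
    rng = np.random.default_rng(7)
    y_vals = rng.normal(size=25)
    block, meta = make_block_meta(rng, 5, y_vals)
    block.data.loc["f2"] = 1.0
    y = pd.Series(y_vals, index=block.sample_ids)
    ranked, _ = pathway_correlations("m", y, ["f1", "f2"], [block], meta)
    assert list(ranked["target_id"]) == ["f1"]


def test_pathway_keeps_rank_boundary_ties():
    y = pd.Series(np.arange(25, dtype=float), index=[f"s{j}" for j in range(25)])
    rows = {f"f{i}": np.arange(25, dtype=float) * (i + 1) for i in range(12)}
    block = OmicsBlock("proteome", pd.DataFrame(rows, index=y.index).T)
    meta = {f: FeatureMeta(f, "protein", "1.1", True) for f in rows}
    ranked, _ = pathway_correlations("m", y, list(rows), [block], meta,
                                     ScreenParams(top_k=10))
    assert len(ranked) == 12  # all |rho| = 1: the rank-10 tie keeps everyone
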