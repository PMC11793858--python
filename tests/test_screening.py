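"""Rank-test oracles (enumeration / permutation), BH behaviour and the
screening report machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata

import physioscreen as ps
from physioscreen.screening import (
    BA_PAIRS,
    OA_PAIRS,
    ScreeningConfig,
    significance_counts,
)


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------

def kw_h_statistic(groups):
    """Kruskal-Wallis H from the mid-rank formula, with tie correction."""
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)
    n = pooled.size
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


def kw_permutation_p(groups, n_perm=100_000, seed=0):
    """Monte-Carlo permutation p-value of the H statistic."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    h_obs = kw_h_statistic(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        if kw_h_statistic(parts) >= h_obs - 1e-12:
            count += 1
    return count / n_perm


def mw_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration of rank splits."""
    nx = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    mean_u = nx * len(y) / 2
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), nx):
        u = ranks[list(comb)].sum() - nx * (nx + 1) / 2
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def bh_stepup(pvals, q):
    """Direct Benjamini-Hochberg step-up implementation."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = p.size
    reject = np.zeros(m, dtype=bool)
    largest = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * q / m:
            largest = i
    reject[order[:largest]] = True
    return reject


# ----------------------------------------------------------------------
# Kruskal-Wallis
# ----------------------------------------------------------------------

def test_kw_hand_example():
    res = ps.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert res.statistic == pytest.approx(32 / 7)


def test_kw_identical_groups_degenerate():
    res = ps.kruskal_wallis([[3.0, 3.0], [3.0, 3.0]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kw_empty_group_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        ps.kruskal_wallis([[1, 2], []])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_kw_p_matches_permutation_oracle(seed):
    """Chi-square p agrees with the permutation distribution of H within
    Monte-Carlo error for small tie-free groups."""
    rng = np.random.default_rng(seed)
    sizes = rng.integers(4, 7, size=3)
    groups = [list(rng.normal(0.4 * i, 1.0, size=s)) for i, s in enumerate(sizes)]
    res = ps.kruskal_wallis(groups)
    n_perm = 20_000
    p_perm = kw_permutation_p(groups, n_perm=n_perm, seed=seed)
    se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
    # the chi-square approximation carries its own small-sample bias, so
    # allow 3 binomial SEs plus a 0.02 approximation margin
    assert abs(res.p_value - p_perm) < 3 * se + 0.02


# ----------------------------------------------------------------------
# Mann-Whitney
# ----------------------------------------------------------------------

def test_mw_hand_example_exact():
    res = ps.mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)
    assert res.method == "mann-whitney-exact"


def test_mw_identical_samples_p_one():
    res = ps.mann_whitney_u([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    assert res.p_value == 1.0


@pytest.mark.parametrize("seed", range(5))
def test_mw_exact_matches_enumeration_oracle(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, size=int(rng.integers(3, 7)))
    y = rng.normal(0.8, 1, size=int(rng.integers(3, 7)))
    res = ps.mann_whitney_u(x, y)
    assert res.method == "mann-whitney-exact"
    assert res.p_value == pytest.approx(mw_exact_p(x, y), abs=1e-12)


@given(st.integers(0, 1000))
def test_mw_u_identity(seed):
    """U_x + U_y = n1 * n2."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=int(rng.integers(2, 12)))
    y = rng.normal(size=int(rng.integers(2, 12)))
    u_x = ps.mann_whitney_u(x, y).statistic
    u_y = ps.mann_whitney_u(y, x).statistic
    assert u_x + u_y == pytest.approx(len(x) * len(y))


@pytest.mark.parametrize("seed", range(8))
def test_mw_normal_approximation_close_to_exact(seed):
    """For tie-free samples with n <= 8, the continuity-corrected normal
    approximation stays within 0.02 of the exact enumeration p."""
    rng = np.random.default_rng(100 + seed)
    x = rng.normal(0, 1, size=int(rng.integers(4, 9)))
    y = rng.normal(0.5, 1, size=int(rng.integers(4, 9)))
    exact = ps.mann_whitney_u(x, y, exact_threshold=8)
    approx = ps.mann_whitney_u(x, y, exact_threshold=0)
    assert exact.method == "mann-whitney-exact"
    assert approx.method == "mann-whitney-normal"
    assert abs(exact.p_value - approx.p_value) < 0.02


# ----------------------------------------------------------------------
# Benjamini-Hochberg
# ----------------------------------------------------------------------

def test_bh_all_rejected_example():
    reject, _ = ps.bh_adjust([0.01, 0.02, 0.03, 0.04], q=0.05)
    assert reject.all()


def test_bh_none_rejected():
    reject, _ = ps.bh_adjust([0.9, 0.95], q=0.05)
    assert not reject.any()


def test_bh_single_p_reduces_to_raw_test():
    reject, p_adj = ps.bh_adjust([0.04], q=0.05)
    assert reject[0]
    assert p_adj[0] == pytest.approx(0.04)


@given(st.integers(0, 500))
def test_bh_matches_stepup_oracle_and_never_exceeds_uncorrected(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0, 1, size=int(rng.integers(1, 20)))
    reject, p_adj = ps.bh_adjust(p, q=0.05)
    np.testing.assert_array_equal(reject, bh_stepup(p, 0.05))
    assert reject.sum() <= (p <= 0.05).sum()
    # adjusted p monotone in raw-p order
    order = np.argsort(p)
    assert np.all(np.diff(p_adj[order]) >= -1e-12)


# ----------------------------------------------------------------------
# run_screening and summaries
# ----------------------------------------------------------------------

def build_table(seed=0, shifted=(), effect_sd=0.0, test="t"):
    features, labels = ps.simulate_feature_table(
        ps.FEATURE_NAMES, tests=(test,), shifted_features=shifted,
        effect_sd=effect_sd, seed=seed)
    return ps.build_feature_tables(features, labels)[test]


def test_pair_counts_ba_vs_oa():
    table = build_table(seed=1)
    ba = ps.run_screening(table, ScreeningConfig(mode="BA"))
    oa = ps.run_screening(table, ScreeningConfig(mode="OA"))
    assert all(len(s.pairs) == 4 for s in ba.features.values())
    assert all(len(s.pairs) == 10 for s in oa.features.values())
    assert BA_PAIRS == tuple((0, c) for c in (1, 2, 3, 4))
    assert len(OA_PAIRS) == 10


def test_ba_counts_never_exceed_oa_counts():
    table = build_table(seed=2, shifted=("scl_mean", "pnn50"), effect_sd=2.0)
    ba = ps.run_screening(table, ScreeningConfig(mode="BA"))
    oa = ps.run_screening(table, ScreeningConfig(mode="OA"))
    for n in (1, 2, 3):
        c_ba = significance_counts(ba).set_index("row").loc[f"feature_significance_gt{n}", "count"]
        c_oa = significance_counts(oa).set_index("row").loc[f"feature_significance_gt{n}", "count"]
        assert c_ba <= c_oa


def test_significance_count_threshold_semantics():
    table = build_table(seed=3, shifted=("scl_mean",), effect_sd=3.0)
    report = ps.run_screening(table, ScreeningConfig(mode="BA"))
    counts = significance_counts(report).set_index("row")["count"]
    # monotone non-increasing in n
    vals = [counts[f"feature_significance_gt{n}"] for n in (1, 2, 3)]
    assert vals == sorted(vals, reverse=True)
    # the strongly shifted feature is significant in all four pairs
    assert report.features["scl_mean"].n_significant_pairs == 4


def test_small_class_skipped_and_logged():
    table = build_table(seed=4)
    # remove (almost) all class-3 rows for one feature
    df = table.data
    drop = (df["class"] == 3) & (df.feature == "pnn50")
    df.loc[drop, "normalized"] = np.nan
    report = ps.run_screening(table, ScreeningConfig(mode="BA"))
    assert (0, 3) in report.features["pnn50"].skipped_pairs


def test_kw_two_groups_orders_like_mw():
    """With two groups, Kruskal-Wallis and Mann-Whitney produce the same
    ranking of p-values across datasets."""
    rng = np.random.default_rng(0)
    kw_p, mw_p = [], []
    for _ in range(20):
        x = rng.normal(0, 1, 15)
        y = rng.normal(rng.uniform(0, 1.2), 1, 15)
        kw_p.append(ps.kruskal_wallis([x, y]).p_value)
        mw_p.append(ps.mann_whitney_u(x, y, exact_threshold=0).p_value)
    np.testing.assert_array_equal(np.argsort(kw_p), np.argsort(mw_p))


def test_bullet_matrix_common_list_logic():
    planted = ("scl_mean", "temp_delta")
    reports = {}
    for i, test in enumerate(("a", "b", "c", "d")):
        # plant both features in every test except: drop temp_delta in test d
        shifted = planted if test != "d" else ("scl_mean",)
        table = build_table(seed=10 + i, shifted=shifted, effect_sd=3.0, test=test)
        reports[test] = ps.run_screening(table, ScreeningConfig(mode="BA"))
    matrix, common = ps.bullet_matrix(reports)
    assert "scl_mean" in common
    assert "temp_delta" not in common  # bulleted in 3 of 4 tests only
    assert matrix.shape == (43, 4)


def test_bullet_matrix_requires_ba_mode():
    table = build_table(seed=20, test="a")
    rep = ps.run_screening(table, ScreeningConfig(mode="OA"))
    with pytest.raises(ValueError, match="BA"):
        ps.bullet_matrix({"a": rep})


def test_report_json_roundtrip(tmp_path):
    table = build_table(seed=5)
    report = ps.run_screening(table, ScreeningConfig(mode="BA"))
    path = tmp_path / "report.json"
    report.to_json(path)
    import json
    with open(path) as fh:
        payload = json.load(fh)
    assert payload["mode"] == "BA"
    assert len(payload["features"]) == 43
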