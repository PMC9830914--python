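"""Normalization, median CIs and the hypothesis-test layer."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popdcquant import stats


# ----------------------------------------------------------- normalization


def test_control_normalization_maps_control_median_to_one():
    rng = np.random.default_rng(0)
    control = rng.lognormal(0, 0.3, 200)
    normed = stats.normalize_to_control(control, control)
    assert np.median(normed) == pytest.approx(1.0)


def test_normalization_by_direct_division_oracle():
    control = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    values = 2.0 * control
    normed = stats.normalize_to_control(values, control)
    np.testing.assert_allclose(normed, values / 3.0)
    assert np.median(normed) == pytest.approx(2.0)


def test_normalization_idempotent_and_scale_invariant():
    rng = np.random.default_rng(1)
    control = rng.lognormal(0, 0.2, 50)
    values = rng.lognormal(0.3, 0.2, 50)
    once = stats.normalize_to_control(values, control)
    ctrl_once = stats.normalize_to_control(control, control)
    twice = stats.normalize_to_control(once, ctrl_once)
    np.testing.assert_allclose(once, twice)
    scaled = stats.normalize_to_control(7.7 * values, 7.7 * control)
    np.testing.assert_allclose(once, scaled)


def test_normalization_errors():
    with pytest.raises(stats.NormalizationError):
        stats.normalize_to_control([1.0], [])
    with pytest.raises(stats.NormalizationError):
        stats.normalize_to_control([1.0], [0.0, 0.0, 0.0])


# --------------------------------------------------------------- median CI


def test_median_ci_brackets_symmetric_sample():
    med, lo, hi = stats.median_ci(np.arange(1.0, 100.0))
    assert med == 50.0 and lo < 50.0 < hi


def test_median_ci_constant_sample_zero_width():
    med, lo, hi = stats.median_ci(np.full(30, 2.5))
    assert med == lo == hi == 2.5


def test_median_ci_small_sample_bootstraps_with_warning():
    with pytest.warns(UserWarning):
        med, lo, hi = stats.median_ci([1.0, 2.0, 3.0, 4.0], rng=0)
    assert lo <= med <= hi


def test_median_ci_coverage_near_nominal():
    # coverage simulation against the known lognormal median
    rng = np.random.default_rng(42)
    true_med = np.exp(0.2)
    cover = sum(
        (lambda r: r[1] <= true_med <= r[2])(stats.median_ci(rng.lognormal(0.2, 0.5, 100)))
        for _ in range(400)
    )
    assert cover / 400 == pytest.approx(0.95, abs=0.03)


# ------------------------------------------------------------ Mann-Whitney


def test_mann_whitney_exact_p_matches_enumeration_oracle():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    res = stats.mann_whitney(a, b)
    # independent oracle: enumerate all C(6,3) rank assignments
    pooled = np.array(a + b)
    observed_u = sum(1 for x in a for y in b if x > y)
    us = []
    for idx in itertools.combinations(range(6), 3):
        grp_a = pooled[list(idx)]
        grp_b = pooled[[i for i in range(6) if i not in idx]]
        us.append(sum(1 for x in grp_a for y in grp_b if x > y))
    us = np.array(us)
    d = abs(observed_u - 4.5)  # distance from the null mean n1*n2/2
    p_oracle = np.mean(np.abs(us - 4.5) >= d)
    assert res.p_value == pytest.approx(p_oracle)
    assert res.p_value == pytest.approx(0.1)


def test_mann_whitney_identical_samples_not_significant():
    a = np.arange(10.0)
    res = stats.mann_whitney(a, a)
    assert res.p_value > 0.9


def test_mann_whitney_degenerate_all_tied():
    res = stats.mann_whitney([2.0] * 5, [2.0] * 5)
    assert res.p_value == 1.0
    assert "degenerate_all_tied" in res.flags


def test_mann_whitney_type_one_error_calibrated():
    rng = np.random.default_rng(3)
    rejections = sum(
        stats.mann_whitney(rng.normal(size=100), rng.normal(size=100)).p_value < 0.05
        for _ in range(400)
    )
    assert rejections / 400 == pytest.approx(0.05, abs=0.03)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.floats(min_value=0.1, max_value=5.0), st.floats(min_value=-3, max_value=3))
def test_mann_whitney_invariant_under_monotone_transform(scale, shift):
    rng = np.random.default_rng(9)
    a = rng.normal(0, 1, 15)
    b = rng.normal(0.8, 1, 15)
    p1 = stats.mann_whitney(a, b).p_value
    p2 = stats.mann_whitney(np.exp(scale * a + shift), np.exp(scale * b + shift)).p_value
    assert p1 == pytest.approx(p2)


# ------------------------------------------------------------ Kruskal/Dunn


def test_kruskal_identical_groups_not_significant():
    g = np.arange(30.0)
    res = stats.kruskal_dunn({"a": g, "b": g, "c": g})
    assert res.p_value > 0.9


def test_kruskal_requires_three_groups():
    with pytest.raises(ValueError):
        stats.kruskal_dunn({"a": [1, 2, 3], "b": [4, 5, 6]})


def test_kruskal_tie_corrected_h_matches_hand_formula():
    groups = {
        "a": np.array([1.0, 2.0, 2.0]),
        "b": np.array([2.0, 3.0, 5.0]),
        "c": np.array([5.0, 5.0, 7.0]),
    }
    res = stats.kruskal_dunn(groups)
    # hand computation: H = [12/(N(N+1)) * sum n_i Rbar_i^2 - 3(N+1)] / C
    from scipy.stats import rankdata

    pooled = np.concatenate(list(groups.values()))
    ranks = rankdata(pooled)
    n_tot = len(pooled)
    h = 0.0
    start = 0
    for v in groups.values():
        r = ranks[start : start + len(v)]
        h += len(v) * r.mean() ** 2
        start += len(v)
    h = 12.0 / (n_tot * (n_tot + 1)) * h - 3 * (n_tot + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n_tot**3 - n_tot)
    assert res.statistic == pytest.approx(h / correction)


def test_kruskal_dunn_detects_shifted_group():
    rng = np.random.default_rng(5)
    hits = 0
    for _ in range(40):
        groups = {
            "ctl": rng.normal(0, 1, 50),
            "same": rng.normal(0, 1, 50),
            "shift": rng.normal(1.0, 1, 50),
        }
        res = stats.kruskal_dunn(groups, comparisons=[("ctl", "same"), ("ctl", "shift")])
        hits += res.adjusted_p[1] < 0.05
    assert hits / 40 >= 0.9


# ---------------------------------------------------------- ANOVA/Dunnett


def test_anova_dunnett_degenerate_zero_variance():
    res = stats.anova_dunnett({"a": [2.0, 2.0, 2.0], "b": [2.0, 2.0, 2.0]}, "a")
    assert "degenerate_zero_variance" in res.flags
    assert res.p_value == 1.0


def test_anova_dunnett_detects_two_sd_shift():
    rng = np.random.default_rng(8)
    hits = 0
    for _ in range(40):
        groups = {
            "ctl": rng.normal(0, 1, 15),
            "null": rng.normal(0, 1, 15),
            "shift": rng.normal(2.0, 1, 15),
        }
        res = stats.anova_dunnett(groups, "ctl")
        idx = res.comparisons.index("shift vs ctl")
        hits += res.adjusted_p[idx] < 0.01
    assert hits / 40 >= 0.9


def test_anova_dunnett_familywise_error_controlled():
    rng = np.random.default_rng(12)
    fw = 0
    n_rep = 200
    for _ in range(n_rep):
        groups = {k: rng.normal(0, 1, 9) for k in ("ctl", "a", "b", "c")}
        res = stats.anova_dunnett(groups, "ctl")
        fw += any(p < 0.05 for p in res.adjusted_p)
    assert fw / n_rep <= 0.08


# ------------------------------------------------------------------- Holm


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=8))
def test_holm_adjustment_monotone_and_larger_than_raw(raw):
    from statsmodels.stats.multitest import multipletests

    adj = multipletests(raw, method="holm")[1]
    order = np.argsort(raw)
    assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)
    assert np.all(adj >= np.asarray(raw) - 1e-12)
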