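import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from senequant.benchmark import (
    DonorMetricTable,
    build_report,
    fold_difference,
    fold_range,
    p_to_stars,
    spearman,
    welch_one_tailed,
)


# -- fold differences -------------------------------------------------------


def test_fold_identity():
    assert fold_difference(3.5, 3.5) == pytest.approx(1.0)


def test_fold_range_over_donors():
    assert fold_range([1.757, 2.1, 3.0]) == (1.757, 3.0)


def test_fold_reversal_reported_not_suppressed():
    assert fold_difference(1.0, 0.399) == pytest.approx(0.399)


def test_fold_requires_positive_early_mean():
    with pytest.raises(ValueError):
        fold_difference(0.0, 2.0)
    with pytest.raises(ValueError):
        fold_difference(-1.0, 2.0)


# -- Welch one-tailed -------------------------------------------------------


def test_welch_worked_example_against_t_cdf_oracle():
    """E={1,2,3}, S={4,5,6}: t = 3/sqrt(2/3), df = 4, one-tailed p from the
    t CDF; scipy's Welch test is the independent oracle."""
    res = welch_one_tailed([1, 2, 3], [4, 5, 6])
    t_expected = 3.0 / np.sqrt(2.0 / 3.0)
    assert res.t == pytest.approx(t_expected, abs=1e-6)
    assert res.t == pytest.approx(3.674, abs=1e-3)
    assert res.df == pytest.approx(4.0, abs=1e-9)
    assert res.p == pytest.approx(float(stats.t.sf(t_expected, 4.0)), abs=1e-12)
    assert res.p == pytest.approx(0.0106, abs=2e-4)
    assert res.stars == "*"


def test_welch_identical_groups_is_null():
    res = welch_one_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == 0.0
    assert res.p == pytest.approx(0.5)
    assert res.stars == "ns"


def test_welch_zero_variance_equal_means():
    res = welch_one_tailed([2.0, 2.0], [2.0, 2.0])
    assert (res.t, res.p) == (0.0, 0.5)


def test_welch_requires_two_per_group():
    with pytest.raises(ValueError):
        welch_one_tailed([1.0], [2.0, 3.0])


def test_welch_p_monotone_in_separation():
    rng = np.random.default_rng(0)
    e = rng.normal(0.0, 1.0, 10)
    noise = rng.normal(0.0, 1.0, 10)
    ps = [welch_one_tailed(e, noise + shift).p for shift in (0.0, 0.5, 1.0, 2.0, 4.0)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


@given(
    st.lists(st.floats(-50, 50), min_size=2, max_size=12),
    st.lists(st.floats(-50, 50), min_size=2, max_size=12),
)
def test_welch_matches_scipy(e, s):
    if np.var(e) == 0 and np.var(s) == 0:
        return
    mine = welch_one_tailed(e, s)
    ref = stats.ttest_ind(s, e, equal_var=False, alternative="greater")
    assert mine.t == pytest.approx(ref.statistic, rel=1e-9, abs=1e-9)
    assert mine.p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)


@pytest.mark.parametrize(
    "p,stars",
    [(0.0005, "***"), (0.001, "***"), (0.005, "**"), (0.01, "**"), (0.03, "*"),
     (0.05, "*"), (0.051, "ns"), (0.5, "ns")],
)
def test_star_thresholds_inclusive(p, stars):
    assert p_to_stars(p) == stars


# -- Spearman ---------------------------------------------------------------


def _brute_force_spearman_p(x, y, alternative="two-sided"):
    """Independent oracle: scipy r over every explicit permutation."""
    r_obs = stats.spearmanr(x, y).statistic
    rs = [
        stats.spearmanr(x, perm).statistic
        for perm in itertools.permutations(y)
    ]
    rs = np.array(rs)
    eps = 1e-12
    if alternative == "two-sided":
        count = np.count_nonzero(np.abs(rs) >= abs(r_obs) - eps)
    else:
        count = np.count_nonzero(rs >= r_obs - eps)
    return r_obs, count / len(rs)


def test_spearman_perfect_monotone():
    x = [1.0, 2.0, 5.0, 9.0]
    assert spearman(x, [2.0, 4.0, 4.5, 100.0]).r == pytest.approx(1.0)
    assert spearman(x, [-1.0, -3.0, -7.0, -20.0]).r == pytest.approx(-1.0)


def test_spearman_exact_p_matches_brute_force_n5():
    x = [0.3, 1.2, 0.7, 2.2, 1.9]
    y = [10.0, 14.0, 9.0, 30.0, 31.0]
    res = spearman(x, y)
    r_ref, p_ref = _brute_force_spearman_p(x, y)
    assert res.method == "exact-permutation"
    assert res.r == pytest.approx(r_ref, abs=1e-12)
    assert res.p == pytest.approx(p_ref, abs=1e-12)


@given(
    st.lists(st.integers(min_value=0, max_value=4), min_size=3, max_size=6),
    st.data(),
)
def test_spearman_exact_matches_brute_force_with_ties(x, data):
    y = data.draw(
        st.lists(st.integers(min_value=0, max_value=4), min_size=len(x), max_size=len(x))
    )
    if len(set(x)) == 1 or len(set(y)) == 1:
        return
    res = spearman(x, y)
    r_ref, p_ref = _brute_force_spearman_p(x, y)
    assert res.r == pytest.approx(r_ref, abs=1e-9)
    assert res.p == pytest.approx(p_ref, abs=1e-9)


def test_spearman_invariant_under_monotone_transform():
    rng = np.random.default_rng(8)
    x = rng.normal(size=8)
    y = rng.normal(size=8)
    base = spearman(x, y)
    warped = spearman(np.exp(x), y**3)
    assert warped.r == pytest.approx(base.r, abs=1e-12)
    assert warped.p == pytest.approx(base.p, abs=1e-12)


def test_spearman_constant_input_flagged():
    with pytest.warns(UserWarning, match="constant"):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert not res.defined
    assert np.isnan(res.r)


def test_spearman_large_n_uses_t_approximation():
    rng = np.random.default_rng(9)
    x = rng.normal(size=20)
    y = x + rng.normal(scale=0.5, size=20)
    res = spearman(x, y)
    ref = stats.spearmanr(x, y)
    assert res.method == "t-approx"
    assert res.r == pytest.approx(ref.statistic, abs=1e-12)


# -- report assembly --------------------------------------------------------


def _toy_table(rng, n_donors=4, lipo_shift=2.0):
    table = DonorMetricTable.empty()
    for d in range(n_donors):
        donor = f"d{d}"
        base = 1.0 + 0.4 * d
        bgal_e, bgal_s = 10.0 + d, 55.0 + 2 * d
        table.add(donor, "E", "bgal_pct", bgal_e + rng.normal(0, 0.1, 3))
        table.add(donor, "S", "bgal_pct", bgal_s + rng.normal(0, 0.1, 3))
        table.add(donor, "E", "lipopigment_mean", base * (1 + rng.normal(0, 0.01, 10)))
        table.add(donor, "S", "lipopigment_mean", base * lipo_shift * (1 + rng.normal(0, 0.01, 10)))
    return table


def test_report_recovers_configured_fold():
    table = _toy_table(np.random.default_rng(1))
    report = build_report(table)
    for fold in report.folds["lipopigment_mean"].values():
        assert fold == pytest.approx(2.0, rel=0.1)
    lo, hi = report.fold_ranges["lipopigment_mean"]
    assert lo <= hi


def test_report_benchmark_self_correlation_is_one():
    report = build_report(_toy_table(np.random.default_rng(2)))
    assert report.correlations["bgal_pct"].r == pytest.approx(1.0)


def test_report_excludes_donor_missing_s_row():
    table = _toy_table(np.random.default_rng(3))
    mask = ~((table.summary["donor"] == "d3") & (table.summary["passage"] == "S"))
    table = DonorMetricTable(table.summary[mask].reset_index(drop=True), table.raw)
    with pytest.warns(UserWarning, match="excluded"):
        report = build_report(table)
    assert "d3" in report.excluded_donors
    assert len(report.folds["lipopigment_mean"]) == 3


def test_report_requires_benchmark_metric():
    table = DonorMetricTable.empty()
    table.add("d0", "E", "fsc_mean", [1.0, 2.0])
    table.add("d0", "S", "fsc_mean", [2.0, 3.0])
    with pytest.raises(ValueError, match="bgal_pct"):
        build_report(table)


def test_report_welch_stars_consistent_with_p():
    report = build_report(_toy_table(np.random.default_rng(4)))
    for per_donor in report.welch.values():
        for res in per_donor.values():
            assert res.stars == p_to_stars(res.p)
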