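"""Statistics battery: summaries, Spearman, Wilcoxon, Holm, Fligner-Killeen."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from greenexposure import (
    annual_trend,
    fligner_killeen,
    holm_adjust,
    pairwise_year_tests,
    spearman_matrix,
    summarize,
    wilcoxon_rank_sum,
)
from greenexposure.stats import pairwise_all_radii, summary_table, trend_table


def matrix_from(columns: dict) -> pd.DataFrame:
    """Exposure-matrix-shaped frame from {(year, radius): values}."""
    df = pd.DataFrame(columns)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["year", "radius_m"])
    return df


class TestSummarize:
    def test_symmetric_sample(self):
        s = summarize([1.0, 2.0, 3.0])
        assert s.mean == pytest.approx(2.0)
        assert s.median == pytest.approx(2.0)
        assert s.skewness == pytest.approx(0.0, abs=1e-12)
        # m2 = 2/3, m4 = 2/3 -> g2 = (2/3)/(4/9) - 3 = -1.5
        assert s.kurtosis == pytest.approx(-1.5)

    def test_sd_uses_n_minus_1(self):
        s = summarize([1.0, 2.0, 3.0])
        assert s.sd == pytest.approx(1.0)

    def test_order_statistics(self, rng):
        x = rng.normal(size=200)
        s = summarize(x)
        assert s.min <= s.q25 <= s.median <= s.q75 <= s.max
        assert s.q25 == pytest.approx(np.percentile(x, 25))

    def test_constant_sample_has_undefined_shape(self):
        s = summarize([0.5, 0.5, 0.5])
        assert s.sd == 0.0
        assert np.isnan(s.skewness) and np.isnan(s.kurtosis)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            summarize([np.nan, np.nan])

    def test_moment_oracle(self, rng):
        x = rng.uniform(0, 1, 50)
        s = summarize(x)
        m = x.mean()
        m2 = np.mean((x - m) ** 2)
        m3 = np.mean((x - m) ** 3)
        m4 = np.mean((x - m) ** 4)
        assert s.skewness == pytest.approx(m3 / m2**1.5)
        assert s.kurtosis == pytest.approx(m4 / m2**2 - 3)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == pytest.approx([0.03])

    def test_step_down_by_hand(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_monotone_enforcement(self):
        # the running max keeps adjusted values ordered like the raw ones
        out = holm_adjust([0.01, 0.011, 0.5])
        assert out[0] <= out[1] <= out[2]
        assert out == pytest.approx([0.03, 0.03, 0.5])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_adjust([0.1, 1.2])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_sandwich_bounds(self, pvals):
        adj = holm_adjust(pvals)
        m = len(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= np.minimum(1.0, m * np.asarray(pvals)) + 1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10), st.randoms())
    def test_permutation_equivariance(self, pvals, pyrandom):
        perm = list(range(len(pvals)))
        pyrandom.shuffle(perm)
        direct = holm_adjust(pvals)
        permuted = holm_adjust([pvals[i] for i in perm])
        assert np.allclose([direct[i] for i in perm], permuted)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 40)
        _, adj, _, _ = multipletests(p, method="holm")
        assert holm_adjust(p) == pytest.approx(adj)


def midrank_pearson(x, y):
    """Independent Spearman oracle: Pearson correlation of mid-ranks."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_perfect_monotone(self):
        m = matrix_from({
            (2006, 300.0): [1.0, 2, 3, 5, 9],
            (2007, 300.0): [2.0, 4, 5, 10, 30],
        })
        res = spearman_matrix(m)
        assert res.rho[0, 1] == pytest.approx(1.0)

    def test_perfect_antitone(self):
        m = matrix_from({
            (2006, 300.0): [1.0, 2, 3, 4],
            (2007, 300.0): [4.0, 3, 2, 1],
        })
        assert spearman_matrix(m).rho[0, 1] == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_oracle(self):
        x = [1.0, 2, 2, 4]
        y = [3.0, 1, 1, 2]
        m = matrix_from({(2006, 300.0): x, (2007, 300.0): y})
        assert spearman_matrix(m).rho[0, 1] == pytest.approx(midrank_pearson(x, y))

    def test_pairwise_deletion_of_missing(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.2, size=30)
        y[:4] = np.nan
        m = matrix_from({(2006, 300.0): x, (2007, 300.0): y})
        res = spearman_matrix(m)
        assert res.rho[0, 1] == pytest.approx(midrank_pearson(x[4:], y[4:]))

    def test_constant_column_is_nan_with_warning(self):
        m = matrix_from({
            (2006, 300.0): [1.0, 2, 3, 4],
            (2007, 300.0): [5.0, 5, 5, 5],
        })
        with pytest.warns(RuntimeWarning, match="constant"):
            res = spearman_matrix(m)
        assert np.isnan(res.rho[0, 1])

    def test_adjusted_ge_raw_and_symmetric(self, rng):
        cols = {
            (y, r): rng.normal(size=25)
            for y in (2006, 2007, 2008)
            for r in (300.0, 600.0)
        }
        res = spearman_matrix(matrix_from(cols))
        assert np.allclose(res.rho, res.rho.T)
        assert np.all(np.diag(res.rho) == 1.0)
        off = ~np.eye(len(res.labels), dtype=bool)
        assert np.all(res.p_adj[off] >= res.p_raw[off] - 1e-15)


def ranksum_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating every allocation of pooled ranks."""
    na = len(a)
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    w_obs = ranks[:na].sum()
    mu = na * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), na):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestWilcoxonRankSum:
    def test_identical_samples_not_significant(self, rng):
        x = rng.normal(size=40)
        _, p = wilcoxon_rank_sum(x, x)
        assert p > 0.9

    def test_two_vs_two_exact_third(self):
        w, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert w == 3.0  # ranks 1 + 2
        assert p == pytest.approx(1 / 3)

    def test_exact_path_matches_enumeration(self, rng):
        for _ in range(10):
            na, nb = rng.integers(2, 5, size=2)
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            _, p = wilcoxon_rank_sum(a, b, method="exact")
            assert p == pytest.approx(ranksum_enumeration_oracle(a, b), abs=1e-12)

    def test_asymptotic_close_to_enumeration_for_small_n(self, rng):
        for _ in range(20):
            na = int(rng.integers(3, 6))
            nb = int(rng.integers(3, 11 - na))
            a = rng.normal(size=na)
            b = rng.normal(loc=rng.normal(), size=nb)
            _, p_approx = wilcoxon_rank_sum(a, b, method="asymptotic")
            assert abs(p_approx - ranksum_enumeration_oracle(a, b)) < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_shift_detected(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(loc=2.0, size=60)
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-6


class TestPairwiseYearTests:
    @pytest.fixture
    def twelve_year_matrix(self, rng):
        return matrix_from({
            (y, 300.0): rng.normal(0.55, 0.11, size=40) for y in range(2006, 2018)
        })

    def test_66_entries_for_12_years(self, twelve_year_matrix):
        res = pairwise_year_tests(twelve_year_matrix, 300.0)
        assert len(res.pairs) == 66
        assert np.all(res.p_adj >= res.p_raw - 1e-15)
        assert np.all((res.p_adj >= 0) & (res.p_adj <= 1))

    def test_identical_columns_not_significant(self, rng):
        x = rng.normal(size=30)
        m = matrix_from({(2006, 300.0): x, (2007, 300.0): x.copy()})
        res = pairwise_year_tests(m, 300.0)
        assert res.p_adj[0] > 0.9

    def test_adjustment_matches_step_down_definition(self, twelve_year_matrix):
        res = pairwise_year_tests(twelve_year_matrix, 300.0)
        p = res.p_raw
        m = len(p)
        order = np.argsort(p)
        running = 0.0
        expected = np.empty(m)
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * p[idx]))
            expected[idx] = running
        assert res.p_adj == pytest.approx(expected)

    def test_paired_variant(self, rng):
        x = rng.normal(size=50)
        m = matrix_from({(2006, 300.0): x, (2007, 300.0): x + 0.02})
        unpaired = pairwise_year_tests(m, 300.0, paired=False)
        paired = pairwise_year_tests(m, 300.0, paired=True)
        # a constant within-address shift is invisible to the rank-sum test
        # at this effect size but certain for the signed-rank test
        assert paired.p_raw[0] < unpaired.p_raw[0]
        assert paired.p_raw[0] < 1e-6

    def test_global_family_is_stricter_per_radius(self, rng):
        cols = {}
        for r in (300.0, 600.0):
            for y in (2006, 2007, 2008):
                cols[(y, r)] = rng.normal(y - 2006, 1.0, size=25)
        m = matrix_from(cols)
        per_radius = pairwise_all_radii(m, family="radius")
        global_fam = pairwise_all_radii(m, family="global")
        for r in (300.0, 600.0):
            assert np.all(global_fam[r].p_adj >= per_radius[r].p_adj - 1e-12)


def fligner_oracle(groups):
    """Step-by-step normal-scores computation of the FK statistic."""
    from scipy.stats import rankdata

    devs = [np.abs(np.asarray(g, float) - np.median(g)) for g in groups]
    all_dev = np.concatenate(devs)
    n = all_dev.size
    ranks = rankdata(all_dev)
    scores = norm.ppf(0.5 + ranks / (2.0 * (n + 1)))
    grand = scores.mean()
    v2 = scores.var(ddof=1)
    stat = 0.0
    start = 0
    for g in devs:
        k = g.size
        stat += k * (scores[start : start + k].mean() - grand) ** 2
        start += k
    return stat / v2


class TestFlignerKilleen:
    def test_identical_groups_give_zero_statistic(self):
        g = [1.0, 2.0, 5.0, 9.0]
        res = fligner_killeen([g, list(g)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.pvalue == pytest.approx(1.0)
        assert res.df == 1

    def test_matches_hand_formula(self):
        groups = [[1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0]]
        res = fligner_killeen(groups)
        assert res.statistic == pytest.approx(fligner_oracle(groups), abs=1e-10)

    def test_hand_formula_on_random_groups(self, rng):
        groups = [rng.normal(scale=s, size=12).tolist() for s in (1.0, 1.0, 3.0)]
        res = fligner_killeen(groups)
        assert res.df == 2
        assert res.statistic == pytest.approx(fligner_oracle(groups), abs=1e-10)

    def test_unequal_variances_detected(self, rng):
        a = rng.normal(scale=1.0, size=200)
        b = rng.normal(scale=3.0, size=200)
        assert fligner_killeen([a, b]).pvalue < 1e-6

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            fligner_killeen([[1.0], [2.0, 3.0]])


class TestAnnualTrend:
    def test_constant_means_zero_slope(self):
        m = matrix_from({(y, 300.0): [0.5, 0.5, 0.5] for y in (2006, 2007, 2008)})
        slope, _ = annual_trend(m, 300.0)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_means(self):
        m = matrix_from(
            {(y, 300.0): [0.5 + 0.01 * (y - 2006)] * 4 for y in range(2006, 2012)}
        )
        slope, intercept = annual_trend(m, 300.0)
        assert slope == pytest.approx(0.01)
        assert intercept + 2006 * slope == pytest.approx(0.5)

    def test_matches_normal_equations(self, rng):
        m = matrix_from({(y, 600.0): rng.normal(0.55, 0.1, 20) for y in range(2006, 2018)})
        slope, intercept = annual_trend(m, 600.0)
        years = np.arange(2006, 2018, dtype=float)
        means = np.array([m[(int(y), 600.0)].mean() for y in years])
        xbar, ybar = years.mean(), means.mean()
        beta = np.sum((years - xbar) * (means - ybar)) / np.sum((years - xbar) ** 2)
        assert slope == pytest.approx(beta)
        assert intercept == pytest.approx(ybar - beta * xbar)


def test_summary_and_trend_tables_cover_all_columns(rng):
    m = matrix_from({
        (y, r): rng.normal(0.5, 0.1, 15)
        for y in (2006, 2007)
        for r in (300.0, 600.0, 1000.0)
    })
    st_tab = summary_table(m)
    assert st_tab.shape[0] == 6
    assert set(st_tab["buffer_m"]) == {300.0, 600.0, 1000.0}
    tr = trend_table(m)
    assert list(tr["buffer_m"]) == [300.0, 600.0, 1000.0]
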