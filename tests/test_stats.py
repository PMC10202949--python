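"""Group-comparison statistics, the two-stage FDR procedure, and
correlation/regression results."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from hpcsi.stats import (CorrelationResult, anova_tukey, bky_two_stage,
                         fold_change, kruskal_bky, kruskal_wallis, linreg,
                         p_stars, pearson_corr)


def bky_oracle(pvalues, q):
    """Brute-force two-stage step-up, coded directly from the definition."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    q1 = q / (1.0 + q)

    def bh_reject(alpha):
        order = np.argsort(p, kind="stable")
        k = 0
        for i in range(m):
            if p[order[i]] <= alpha * (i + 1) / m:
                k = i + 1
        rej = np.zeros(m, dtype=bool)
        for i in range(k):
            rej[order[i]] = True
        return rej

    stage1 = bh_reject(q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    m0 = m - r1
    return bh_reject(q1 * m / m0)


class TestFoldChange:
    def test_identical_groups_give_one(self):
        assert fold_change([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_ratio_of_means(self):
        assert fold_change([2, 2, 2], [1, 1, 1]) == 2.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fold_change([1.0], [0.0])


class TestAnovaTukey:
    def test_identical_groups_null(self, rng):
        g = rng.normal(0, 1, 8)
        comp = anova_tukey({"a": g, "b": g.copy(), "c": g.copy()})
        assert comp.statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.pvalue == pytest.approx(1.0)
        assert np.all(comp.contrasts.p_adj > 0.9)

    def test_f_statistic_matches_sum_of_squares_oracle(self):
        groups = {"a": np.array([6.0, 8.0, 4.0, 5.0, 3.0, 4.0]),
                  "b": np.array([8.0, 12.0, 9.0, 11.0, 6.0, 8.0]),
                  "c": np.array([13.0, 9.0, 11.0, 8.0, 7.0, 12.0])}
        comp = anova_tukey(groups)
        # brute force from the between/within sum-of-squares formulas
        all_vals = np.concatenate(list(groups.values()))
        grand = all_vals.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2
                         for g in groups.values())
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        k, n = len(groups), all_vals.size
        f_oracle = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert comp.statistic == pytest.approx(f_oracle, rel=1e-10)

    def test_reports_group_sizes_and_folds(self, rng):
        groups = {"lo": rng.normal(1, 0.1, 6), "hi": rng.normal(2, 0.1, 9)}
        comp = anova_tukey(groups, endpoint="x")
        assert comp.n == (6, 9)
        pair = comp.contrasts.iloc[0]
        expected = fold_change(groups[pair.group_a], groups[pair.group_b])
        assert pair.fold_change == pytest.approx(expected)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": np.array([1.0]), "b": np.array([1.0, 2.0])})

    def test_type_i_error_calibration(self):
        """Null ANOVA rejects ~5% of the time (quick 400-replicate check)."""
        rng = np.random.default_rng(1234)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            f, p = sps.f_oneway(*(rng.normal(0, 1, 8) for _ in range(4)))
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.03 < rate < 0.075


class TestKruskalWallis:
    def test_identical_constants_h_zero(self):
        h, p = kruskal_wallis([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        assert h == 0.0 and p == 1.0

    def test_hand_computed_rank_formula(self):
        """{1,2,3} vs {4,5,6}: ranks 1..6 give H = 12/42*(12+75) - 21."""
        h, _ = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        r1, r2 = 1 + 2 + 3, 4 + 5 + 6
        h_oracle = 12 / (6 * 7) * (r1 ** 2 / 3 + r2 ** 2 / 3) - 3 * 7
        assert h == pytest.approx(h_oracle, rel=1e-12)

    def test_chi2_p_close_to_exhaustive_permutation(self):
        """Exact permutation over all 20-choose-10 splits vs the chi-square
        approximation, in the decision-relevant tail."""
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 10).round(2)
        b = rng.normal(1.0, 1, 10).round(2)
        h_obs, p_chi2 = kruskal_wallis([a, b])
        pool = np.concatenate([a, b])
        ranks = sps.rankdata(pool)
        combs = np.fromiter(
            itertools.chain.from_iterable(
                itertools.combinations(range(20), 10)),
            dtype=np.int64).reshape(-1, 10)
        r1 = ranks[combs].sum(axis=1)
        h_all = 12 / (20 * 21) * (r1 ** 2 / 10
                                  + (ranks.sum() - r1) ** 2 / 10) - 3 * 21
        p_perm = float(np.mean(h_all >= h_obs - 1e-12))
        assert abs(p_chi2 - p_perm) < 0.02

    def test_small_total_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], [2.0, 3.0]])


class TestBkyTwoStage:
    def test_all_ones_reject_nothing(self):
        rej, adj = bky_two_stage(np.ones(6), 0.05)
        assert not rej.any()
        assert np.all(adj == 1.0)

    def test_single_small_p_rejected(self):
        rej, _ = bky_two_stage([0.01], 0.05)
        assert rej.all()

    def test_worked_example_matches_oracle(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074,
             0.205, 0.212, 0.216]
        rej, adj = bky_two_stage(p, 0.05)
        assert np.array_equal(rej, bky_oracle(p, 0.05))
        assert np.array_equal(adj <= 0.05, rej)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            m = int(rng.integers(1, 25))
            p = rng.uniform(0, 1, m) ** rng.uniform(0.3, 3.0)
            q = float(rng.uniform(0.01, 0.2))
            rej, adj = bky_two_stage(p, q)
            assert np.array_equal(rej, bky_oracle(p, q))
            assert np.array_equal(adj <= q, rej)

    def test_matches_statsmodels_reference(self):
        import statsmodels.stats.multitest as mt
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = rng.uniform(0, 1, int(rng.integers(3, 20))) ** 2
            rej, _ = bky_two_stage(p, 0.05)
            rej_sm, *_ = mt.fdrcorrection_twostage(p, 0.05, method="bky",
                                                   maxiter=1)
            assert np.array_equal(rej, rej_sm)

    def test_rejects_superset_of_plain_bh(self):
        """With >= 1 stage-1 rejection and m0 < m, the adaptive step-up
        can only gain power over plain BH."""
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 50:
            p = rng.uniform(0, 1, 12) ** 3
            rej, _ = bky_two_stage(p, 0.05)
            bh = sps.false_discovery_control(p, method="bh") <= 0.05
            q1 = 0.05 / 1.05
            order = np.sort(p)
            stage1_any = np.any(order <= q1 * np.arange(1, 13) / 12)
            if stage1_any and rej.sum() < 12:
                assert np.all(bh <= rej)
                checked += 1

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bky_two_stage([0.5, 1.5], 0.05)
        with pytest.raises(ValueError):
            bky_two_stage([0.5], 0.0)


class TestKruskalBky:
    def test_contrast_count_and_bounds(self, rng):
        groups = {n: rng.normal(i, 1, 8) for i, n in
                  enumerate(["a", "b", "c", "d"])}
        comp = kruskal_bky(groups, endpoint="y")
        assert len(comp.contrasts) == 6
        assert np.all((comp.contrasts.p_adj >= 0)
                      & (comp.contrasts.p_adj <= 1))

    def test_agrees_with_anova_on_separated_groups(self):
        """Both families make the same call on well-separated groups."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            groups = {"a": rng.normal(0, 1, 10), "b": rng.normal(4, 1, 10),
                      "c": rng.normal(8, 1, 10)}
            a = anova_tukey(groups)
            k = kruskal_bky(groups)
            assert (a.pvalue < 0.05) == (k.pvalue < 0.05)


class TestCorrelations:
    def test_perfect_correlation(self):
        x = np.arange(5.0)
        assert pearson_corr(x, x).r == pytest.approx(1.0)
        assert pearson_corr(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        res = pearson_corr([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6)

    def test_pairwise_complete_handling(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, np.nan]
        res = pearson_corr(x, y)
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr([1, 1, 1], [1, 2, 3])

    def test_exact_line_regression(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = linreg(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_null_slope_within_three_se(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 10_000)
        y = rng.normal(0, 1, 10_000)
        res = linreg(x, y)
        se = 1.0 / math.sqrt(10_000)  # slope SE for unit-variance noise
        assert abs(res.slope) < 3 * se

    def test_normal_equations_match_grid_search(self):
        x = np.array([0.0, 0.5, 1.1, 1.9, 3.0])
        y = np.array([1.0, 1.9, 3.4, 4.6, 7.1])
        res = linreg(x, y)
        slopes = np.linspace(res.slope - 0.01, res.slope + 0.01, 201)
        intercepts = np.linspace(res.intercept - 0.01, res.intercept + 0.01,
                                 201)
        ss = np.array([[np.sum((y - s * x - c) ** 2) for c in intercepts]
                       for s in slopes])
        i, j = np.unravel_index(np.argmin(ss), ss.shape)
        assert slopes[i] == pytest.approx(res.slope, abs=1e-6 + 5e-5)
        assert intercepts[j] == pytest.approx(res.intercept, abs=1e-6 + 5e-5)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linreg([1, 1, 1], [1, 2, 3])

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            CorrelationResult("x", "y", "pearson", 5, r=1.5)


def test_p_star_rendering():
    assert p_stars(0.2) == ""
    assert p_stars(0.04) == "*"
    assert p_stars(0.009) == "**"
    assert p_stars(0.0009) == "***"
    assert p_stars(0.00005) == "****"
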