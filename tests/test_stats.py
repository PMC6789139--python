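"""Statistical layer against hand computations and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from raphequant import stats


def bh_bruteforce(p):
    """Independent BH oracle: min over suffix of m*p_(j)/j, input order kept."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


class TestWelchFromSummaries:
    def test_penetrance_comparison_from_printed_summaries(self):
        r = stats.welch_t_from_summaries(323.8, 43.3, 5, 166.8, 29.9, 5)
        assert round(r.statistic, 3) == 2.984
        assert round(r.df, 3) == 7.108  # 4(a+b)^2/(a^2+b^2), a=43.3^2, b=29.9^2
        assert r.p < 0.05

    def test_equal_summaries_give_t_zero(self):
        r = stats.welch_t_from_summaries(5.0, 1.0, 4, 5.0, 1.0, 4)
        assert r.statistic == 0.0 and r.p == pytest.approx(1.0)

    def test_matches_raw_data_welch(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(3, 12)), int(rng.integers(3, 12))
            x = rng.normal(5, 2, n1)
            y = rng.normal(4, 3, n2)
            s = stats.welch_t_from_summaries(
                x.mean(), x.std(ddof=1) / np.sqrt(n1), n1,
                y.mean(), y.std(ddof=1) / np.sqrt(n2), n2)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert abs(s.statistic - ref.statistic) < 1e-10
            assert abs(s.p - ref.pvalue) < 1e-10

    def test_df_within_welch_bounds(self, rng):
        for _ in range(50):
            n1, n2 = int(rng.integers(2, 10)), int(rng.integers(2, 10))
            s1, s2 = rng.uniform(0.1, 5, 2)
            r = stats.welch_t_from_summaries(0, s1, n1, 1, s2, n2)
            assert min(n1, n2) - 1 <= r.df <= n1 + n2 - 2 + 1e-9

    def test_degenerate_sems_rejected(self):
        with pytest.raises(ValueError):
            stats.welch_t_from_summaries(1.0, 0.0, 5, 1.0, 0.0, 5)

    def test_type_one_error_near_nominal_under_null(self, rng):
        hits = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0, 1, 6)
            r = stats.welch_t_from_summaries(
                x.mean(), x.std(ddof=1) / np.sqrt(6), 6,
                y.mean(), y.std(ddof=1) / np.sqrt(6), 6)
            hits += r.p < 0.05
        assert 0.035 <= hits / reps <= 0.065


class TestPairedT:
    def test_identical_vectors_give_zero(self):
        r = stats.paired_t([1, 2, 3], [1, 2, 3])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_hand_computed_two_pairs(self):
        # differences {1, 3}: mean 2, sd sqrt(2), SE 1 -> t = 2, df = 1
        r = stats.paired_t([2.0, 4.0], [1.0, 1.0])
        assert r.statistic == pytest.approx(2.0)
        assert r.df == 1.0

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            stats.paired_t([1.0], [2.0])


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        g = [np.array([1.0, 2, 3])] * 3
        r = stats.oneway_anova(g)
        assert r.statistic == 0.0 and r.p == 1.0

    def test_f_matches_bruteforce_ss(self, rng):
        groups = [rng.normal(m, 1, 4) for m in (0, 3, 6)]
        allv = np.concatenate(groups)
        ssb = sum(4 * (g.mean() - allv.mean()) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ssb / 2) / (ssw / 9)
        r = stats.oneway_anova(groups)
        assert r.statistic == pytest.approx(f_hand, rel=1e-12)
        assert r.df == (2.0, 9.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            stats.oneway_anova([np.array([1.0, 2])])

    def test_tukey_flags_separated_pair(self, rng):
        groups = [rng.normal(0, 1, 6), rng.normal(0.2, 1, 6),
                  rng.normal(8, 1, 6)]
        res = stats.tukey_hsd(groups, labels=["a", "b", "c"])
        by_name = {r.name: r for r in res}
        assert by_name["tukey a vs c"].p < 0.001
        assert by_name["tukey a vs b"].p > 0.05

    def test_twoway_constant_response_all_f_zero(self):
        r = stats.twoway_anova([5.0] * 8, ["a", "a", "b", "b"] * 2,
                               ["x", "y"] * 4)
        assert all(v.statistic == 0.0 for v in r.values())

    def test_twoway_additive_noiseless_interaction_zero(self):
        a = np.repeat(["a", "b"], 4)
        b = np.tile(["x", "y"], 4)
        y = 1.0 * (a == "b") + 2.0 * (b == "y")
        r = stats.twoway_anova(y, a, b)
        assert r["A:B"].statistic == 0.0
        assert r["A"].statistic > 0 or np.isinf(r["A"].statistic)

    def test_twoway_matches_projection_oracle(self, rng):
        # balanced 2x3, 4 replicates: classical cell-mean decomposition
        la = np.repeat(["a1", "a2"], 12)
        lb = np.tile(np.repeat(["b1", "b2", "b3"], 4), 2)
        y = (rng.normal(0, 1, 24) + 2.0 * (la == "a2")
             + np.select([lb == "b2", lb == "b3"], [1.0, 3.0], 0.0))
        grand = y.mean()
        ss_a = sum(12 * (y[la == v].mean() - grand) ** 2 for v in ("a1", "a2"))
        ss_b = sum(8 * (y[lb == v].mean() - grand) ** 2
                   for v in ("b1", "b2", "b3"))
        ss_ab = 0.0
        ss_res = 0.0
        for va in ("a1", "a2"):
            for vb in ("b1", "b2", "b3"):
                cell = y[(la == va) & (lb == vb)]
                ss_ab += 4 * (cell.mean() - y[la == va].mean()
                              - y[lb == vb].mean() + grand) ** 2
                ss_res += ((cell - cell.mean()) ** 2).sum()
        f_a = (ss_a / 1) / (ss_res / 18)
        f_b = (ss_b / 2) / (ss_res / 18)
        f_ab = (ss_ab / 2) / (ss_res / 18)
        r = stats.twoway_anova(y, la, lb)
        assert r["A"].statistic == pytest.approx(f_a, abs=1e-8)
        assert r["B"].statistic == pytest.approx(f_b, abs=1e-8)
        assert r["A:B"].statistic == pytest.approx(f_ab, abs=1e-8)


class TestBoxCox:
    def test_lambda_one_is_shift(self):
        x = np.array([1.0, 2.0, 5.0])
        assert np.allclose(stats.boxcox_transform(x, 1.0), x - 1.0)

    def test_lambda_zero_is_log(self):
        x = np.array([1.0, 2.0, 5.0])
        assert np.allclose(stats.boxcox_transform(x, 0.0), np.log(x))

    def test_mle_near_zero_for_lognormal(self, rng):
        x = rng.lognormal(0.0, 1.0, 200)
        fit = stats.boxcox(x)
        assert abs(fit.lmbda) <= 0.15

    def test_mle_maximizes_profile_likelihood(self, rng):
        x = rng.lognormal(1.0, 0.5, 60)
        fit = stats.boxcox(x)
        for probe in np.linspace(-2, 2, 9):
            assert fit.loglik >= sps.boxcox_llf(probe, x) - 1e-6

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            stats.boxcox([1.0, 0.0, 2.0])


class TestSpearmanGate:
    def test_constant_absolute_residuals(self):
        r = stats.spearman_hetero_test([1, -1, 1, -1], [1, 2, 3, 4])
        assert r.statistic == 0.0 and r.p == 1.0

    def test_increasing_spread_gives_rho_one(self):
        r = stats.spearman_hetero_test([0.1, -0.5, 1.0, -2.0], [1, 2, 3, 4])
        assert r.statistic == pytest.approx(1.0)

    def test_matches_rank_formula(self, rng):
        resid = rng.normal(0, 1, 30)
        fitted = rng.normal(5, 2, 30)
        r = stats.spearman_hetero_test(resid, fitted)
        ranks = lambda v: np.argsort(np.argsort(v)) + 1.0
        rho_hand = np.corrcoef(ranks(np.abs(resid)), ranks(fitted))[0, 1]
        assert r.statistic == pytest.approx(rho_hand, abs=1e-12)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert stats.benjamini_hochberg([0.031])[0] == pytest.approx(0.031)

    def test_all_equal_stay_equal(self):
        adj = stats.benjamini_hochberg([0.02] * 5)
        assert np.allclose(adj, 0.02)

    def test_hand_stepup_example(self):
        adj = stats.benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.allclose(stats.benjamini_hochberg(p), bh_bruteforce(p),
                               atol=1e-12)

    def test_adjusted_monotone_in_rank(self, rng):
        p = rng.random(25)
        adj = stats.benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_rejection_set_stable_under_readjustment(self, rng):
        p = rng.random(20) * 0.2
        adj = stats.benjamini_hochberg(p)
        re_adj = stats.benjamini_hochberg(adj)
        assert np.array_equal(adj <= 0.05, re_adj <= 0.05)

    def test_family_helper_sets_adjusted_p(self):
        fam = [stats.TestResult("t1", 1.0, 3.0, 0.01),
               stats.TestResult("t2", 1.0, 3.0, 0.04)]
        stats.adjust_family(fam)
        assert fam[0].p_adjusted == pytest.approx(0.02)
        assert fam[1].p_adjusted == pytest.approx(0.04)
        assert fam[0].stars == "*"
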