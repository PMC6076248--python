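import numpy as np
import pytest
from scipy import stats

from chronolux import inference as inf


class TestShapiroWilk:
    def test_normal_quantile_grid_is_near_perfectly_normal(self):
        """Values placed on exact normal quantiles (n=8) give W > 0.99."""
        x = stats.norm.ppf((np.arange(1, 9) - 0.375) / (8 + 0.25))
        w, p = inf.shapiro_wilk(x)
        assert w > 0.99

    def test_strongly_skewed_sample_fails(self):
        x = np.exp(np.linspace(0.0, 5.0, 20))
        w, p = inf.shapiro_wilk(x)
        assert p < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            inf.shapiro_wilk(np.full(8, 3.14))

    @pytest.mark.parametrize("n", [2, 51])
    def test_sample_size_range_enforced(self, n):
        with pytest.raises(ValueError, match="3 <= n <= 50"):
            inf.shapiro_wilk(np.arange(n, dtype=float))


class TestBootstrapPairedTest:
    def test_identical_pairs_are_maximally_null(self):
        pairs = inf.PairedSamples(np.arange(8.0), np.arange(8.0))
        res = inf.bootstrap_paired_test(pairs, n_iter=1000, seed=0)
        assert res.observed_mean_diff == 0.0
        assert res.p_value == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        pairs = inf.PairedSamples(rng.normal(size=8), rng.normal(size=8))
        r1 = inf.bootstrap_paired_test(pairs, n_iter=20_000, seed=9)
        r2 = inf.bootstrap_paired_test(pairs, n_iter=20_000, seed=9)
        assert r1 == r2

    def test_invariant_to_pair_order(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=8), rng.normal(size=8)
        perm = rng.permutation(8)
        r1 = inf.bootstrap_paired_test(inf.PairedSamples(a, b), n_iter=20_000, seed=3)
        r2 = inf.bootstrap_paired_test(
            inf.PairedSamples(a[perm], b[perm]), n_iter=20_000, seed=3
        )
        # same multiset of differences, same seed -> same resampling law;
        # p-values agree within Monte-Carlo error
        assert r1.p_value == pytest.approx(r2.p_value, abs=0.01)

    def test_seed_to_seed_stability_at_full_iterations(self):
        """Two independent 100,000-iteration runs differ in p by < 0.005."""
        rng = np.random.default_rng(4)
        a = rng.normal(1056.0, 45.0, size=8)
        b = a + rng.normal(26.0, 15.0, size=8)
        pairs = inf.PairedSamples(a, b)
        p1 = inf.bootstrap_paired_test(pairs, n_iter=100_000, seed=1).p_value
        p2 = inf.bootstrap_paired_test(pairs, n_iter=100_000, seed=2).p_value
        assert abs(p1 - p2) < 0.005

    def test_ci_brackets_bootstrap_mean(self):
        rng = np.random.default_rng(5)
        pairs = inf.PairedSamples(rng.normal(size=10), rng.normal(size=10))
        res = inf.bootstrap_paired_test(pairs, n_iter=10_000, seed=6)
        lo, hi = res.ci95
        assert lo <= res.bootstrapped_mean <= hi

    def test_minimum_pairs_enforced(self):
        pairs = inf.PairedSamples(np.arange(3.0), np.zeros(3))
        with pytest.raises(ValueError, match=">= 4"):
            inf.bootstrap_paired_test(pairs)

    def test_zero_variance_nonzero_differences_rejected(self):
        pairs = inf.PairedSamples(np.full(8, 2.0), np.zeros(8))
        with pytest.raises(ValueError, match="zero-variance"):
            inf.bootstrap_paired_test(pairs, n_iter=1000)


class TestPairedT:
    def test_zero_mean_differences(self):
        pairs = inf.PairedSamples(np.array([-1.0, 0.0, 1.0, 0.0]), np.zeros(4))
        t, df, p, ci = inf.paired_t_test(pairs)
        assert t == 0.0 and p == pytest.approx(1.0) and df == 3

    def test_matches_textbook_formula_and_scipy(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=12), rng.normal(size=12)
        t, df, p, ci = inf.paired_t_test(inf.PairedSamples(a, b))
        d = a - b
        t_hand = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_hand, abs=1e-12)
        res = stats.ttest_rel(a, b)
        assert t == pytest.approx(res.statistic, abs=1e-12)
        assert p == pytest.approx(res.pvalue, abs=1e-12)
        lo, hi = res.confidence_interval(0.95)
        assert ci[0] == pytest.approx(lo, abs=1e-10)
        assert ci[1] == pytest.approx(hi, abs=1e-10)

    def test_zero_variance_rejected(self):
        pairs = inf.PairedSamples(np.full(5, 1.0), np.zeros(5))
        with pytest.raises(ValueError, match="zero-variance"):
            inf.paired_t_test(pairs)


class TestRmAnova:
    def test_identical_condition_columns_give_zero_F(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        res = inf.rm_anova_oneway(np.column_stack([col, col, col]))
        assert res.F == 0.0
        assert res.partial_eta_sq == 0.0

    def test_small_table_matches_hand_computed_sums(self):
        """3 participants x 3 conditions against the definitional SS formulas."""
        x = np.array([[1.0, 2.0, 4.0], [2.0, 4.0, 5.0], [3.0, 3.0, 6.0]])
        res = inf.rm_anova_oneway(x)
        grand = x.mean()
        ss_cond = 3 * np.sum((x.mean(axis=0) - grand) ** 2)
        ss_subj = 3 * np.sum((x.mean(axis=1) - grand) ** 2)
        ss_err = np.sum((x - grand) ** 2) - ss_cond - ss_subj
        assert res.ss_conditions == pytest.approx(ss_cond, abs=1e-12)
        assert res.F == pytest.approx((ss_cond / 2) / (ss_err / 4), abs=1e-12)
        assert res.df_effect == 2 and res.df_error == 4
        assert res.partial_eta_sq == pytest.approx(ss_cond / (ss_cond + ss_err))

    def test_two_conditions_reduce_to_squared_paired_t(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=8), rng.normal(size=8)
        res = inf.rm_anova_oneway(np.column_stack([a, b]))
        t, df, p, _ = inf.paired_t_test(inf.PairedSamples(a, b))
        assert res.F == pytest.approx(t**2, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_agrees_with_pingouin(self):
        """Independent cross-check of F, dfs and partial eta squared."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(9)
        x = rng.normal(size=(8, 3)) + np.array([0.0, 0.3, 0.6])
        res = inf.rm_anova_oneway(x)
        long = pd.DataFrame(
            {
                "y": x.ravel(),
                "cond": np.tile(np.arange(3), 8),
                "subj": np.repeat(np.arange(8), 3),
            }
        )
        table = pg.rm_anova(data=long, dv="y", within="cond", subject="subj",
                            detailed=True, effsize="np2")
        assert res.F == pytest.approx(table.loc[0, "F"], rel=1e-9)
        assert res.p_value == pytest.approx(table.loc[0, "p_unc"], rel=1e-9)
        assert res.partial_eta_sq == pytest.approx(table.loc[0, "np2"], rel=1e-9)
        assert (res.df_effect, res.df_error) == (table.loc[0, "DF"], table.loc[1, "DF"])

    def test_incomplete_table_rejected(self):
        x = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError, match="incomplete"):
            inf.rm_anova_oneway(x)


class TestBonferroni:
    def test_correction_is_min_one_three_raw(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(8, 3))
        pairwise = inf.bonferroni_pairwise(x)
        assert len(pairwise) == 3
        for pw in pairwise:
            assert pw.p_corrected == pytest.approx(min(1.0, 3 * pw.p_uncorrected))

    def test_identical_conditions_are_never_significant(self):
        rng = np.random.default_rng(11)
        col = np.array([1.0, 2.0, 3.0, 5.0])
        noisy = col + rng.normal(0.0, 1.0, size=4)
        pairwise = inf.bonferroni_pairwise(np.column_stack([col, col, noisy]))
        identical = [pw for pw in pairwise if pw.pair == ("C1", "C2")][0]
        assert identical.t == 0.0 and identical.p_corrected == 1.0

    def test_injected_difference_detected_with_high_power(self):
        """One pair differing by 10x the noise SD is flagged in >= 95% of runs."""
        rng = np.random.default_rng(12)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            base = rng.normal(0.0, 1.0, size=(8, 3))
            base[:, 2] += 10.0
            pairwise = inf.bonferroni_pairwise(base)
            flagged = {pw.pair: pw.p_corrected < 0.05 for pw in pairwise}
            hits += flagged[("C1", "C3")] and flagged[("C2", "C3")]
        assert hits / n_sim >= 0.95


class TestWelchFromSummaries:
    def test_equal_means_give_zero_t(self):
        res = inf.welch_t_from_summaries(5.0, 1.0, 8, 5.0, 2.0, 8)
        assert res.t == 0.0

    def test_matches_sample_level_welch(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0.0, 1.0, size=8)
        b = rng.normal(0.5, 2.0, size=12)
        res = inf.welch_t_from_summaries(
            a.mean(), a.std(ddof=1) / np.sqrt(len(a)), len(a),
            b.mean(), b.std(ddof=1) / np.sqrt(len(b)), len(b),
        )
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        assert res.df == pytest.approx(ref.df, abs=1e-10)

    def test_equal_n_equal_se_df_closed_form(self):
        res = inf.welch_t_from_summaries(1.0, 0.5, 8, 0.0, 0.5, 8)
        assert res.df == pytest.approx(2 * (8 - 1), abs=1e-12)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            inf.welch_t_from_summaries(1.0, 0.0, 8, 0.0, 1.0, 8)
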