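import numpy as np
import pandas as pd
import pytest

from chronolux import psychometric as psy
from chronolux.simulate import ObserverModel, SessionDesign, simulate_session

from conftest import grid_search_weibull_mle


def make_counts(durations, alpha, beta, n=42, rng=None, lapse=0.0):
    p = psy.weibull_cdf(durations, alpha, beta, lapse)
    if rng is None:
        k = np.round(n * p)
    else:
        k = rng.binomial(n, p).astype(float)
    return psy.PsychometricData(durations, k, np.full_like(durations, float(n)))


class TestAggregateTrials:
    def test_session_aggregates_to_42_per_level(self, design, durations):
        trials = simulate_session(design, ObserverModel(pse_ms=1050.0), "blue", seed=0)
        agg = psy.aggregate_trials(trials)
        assert len(agg.durations_ms) == 9
        assert (agg.n_total == 42).all()
        np.testing.assert_allclose(agg.durations_ms, durations)

    def test_all_longer_responses(self, durations):
        df = pd.DataFrame(
            {"oddball_duration_ms": np.repeat(durations, 3), "response": "longer"}
        )
        agg = psy.aggregate_trials(df)
        np.testing.assert_array_equal(agg.n_longer, agg.n_total)

    def test_additivity_under_concatenation(self, design):
        obs = ObserverModel(pse_ms=1050.0)
        t1 = simulate_session(design, obs, "blue", seed=1)
        t2 = simulate_session(design, obs, "blue", seed=2)
        a1 = psy.aggregate_trials(t1)
        a2 = psy.aggregate_trials(t2)
        both = psy.aggregate_trials(pd.concat([t1, t2], ignore_index=True))
        np.testing.assert_array_equal(both.n_longer, a1.n_longer + a2.n_longer)
        np.testing.assert_array_equal(both.n_total, a1.n_total + a2.n_total)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            psy.aggregate_trials(pd.DataFrame(columns=["oddball_duration_ms", "response"]))

    def test_pooling_must_be_explicit(self, design):
        obs = ObserverModel(pse_ms=1050.0)
        t1 = simulate_session(design, obs, "blue", seed=1, participant="a")
        t2 = simulate_session(design, obs, "blue", seed=2, participant="b")
        both = pd.concat([t1, t2], ignore_index=True)
        with pytest.raises(ValueError, match="pooled"):
            psy.aggregate_trials(both)
        agg = psy.aggregate_trials(both, participant="pooled")
        assert (agg.n_total == 84).all()


class TestClosedForms:
    @pytest.mark.parametrize("beta", [2.0, 8.0, 20.0])
    def test_pse_is_exact_for_constructed_alpha(self, beta):
        alpha = psy.alpha_for_pse(1050.0, beta)
        assert psy.pse_from_params(alpha, beta) == pytest.approx(1050.0, abs=1e-12)

    def test_doubling_beta_sharpens_the_function(self):
        """At fixed PSE, doubling beta halves-ish the threshold and raises slope."""
        pse = 1050.0
        lo = dict(alpha=psy.alpha_for_pse(pse, 6.0), beta=6.0)
        hi = dict(alpha=psy.alpha_for_pse(pse, 12.0), beta=12.0)
        assert psy.threshold_from_params(**hi) < psy.threshold_from_params(**lo)
        assert psy.slope_at_pse(**hi) > psy.slope_at_pse(**lo)

    def test_quantile_inverts_cdf(self):
        q = psy.weibull_quantile(0.75, 1100.0, 8.0)
        assert psy.weibull_cdf(q, 1100.0, 8.0) == pytest.approx(0.75)


class TestFit:
    def test_noise_free_recovery_within_one_percent(self, durations):
        data = make_counts(durations, alpha=1100.0, beta=8.0)
        res = psy.fit_weibull(data)
        assert res.alpha == pytest.approx(1100.0, rel=0.01)
        assert res.converged

    def test_duration_order_does_not_matter(self, durations):
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(durations))
        p = psy.weibull_cdf(durations, 1100.0, 8.0)
        k = np.round(42 * p)
        d1 = psy.PsychometricData(durations, k, np.full(9, 42.0))
        d2 = psy.PsychometricData(durations[perm], k[perm], np.full(9, 42.0))
        r1, r2 = psy.fit_weibull(d1), psy.fit_weibull(d2)
        assert r1.alpha == pytest.approx(r2.alpha, rel=1e-10)
        assert r1.beta == pytest.approx(r2.beta, rel=1e-10)

    def test_agrees_with_grid_search_oracle(self, durations):
        """MLE matches a brute-force (alpha, beta) grid search within one
        grid step on 20 random small datasets."""
        rng = np.random.default_rng(3)
        n = np.full(9, 42.0)
        for _ in range(20):
            a0 = rng.uniform(950.0, 1250.0)
            b0 = rng.uniform(4.0, 15.0)
            k = rng.binomial(42, psy.weibull_cdf(durations, a0, b0)).astype(float)
            data = psy.PsychometricData(durations, k, n)
            try:
                res = psy.fit_weibull(data)
                k_used, n_used = k, n
            except ValueError:
                res = psy.fit_weibull(data, penalized=True)
                k_used, n_used = psy._penalize(k, n)
            ga, gb = grid_search_weibull_mle(durations, k_used, n_used)
            assert abs(res.alpha - ga) <= 0.5 + 1e-9
            assert abs(res.beta - gb) <= 0.05 + 1e-9

    def test_shift_equivariance(self, durations):
        """Adding 100 ms to every duration shifts the fitted PSE by ~100 ms."""
        data = make_counts(durations, alpha=1100.0, beta=8.0)
        shifted = psy.PsychometricData(
            durations + 100.0, data.n_longer, data.n_total
        )
        pse0 = psy.fit_weibull(data).pse
        pse1 = psy.fit_weibull(shifted).pse
        assert pse1 - pse0 == pytest.approx(100.0, abs=2.0)

    def test_monte_carlo_recovery_median_bias(self, durations):
        """200 binomial simulations at 42 trials/level: median PSE bias < 10 ms."""
        rng = np.random.default_rng(7)
        alpha, beta = psy.alpha_for_pse(1057.0, 8.0), 8.0
        p = psy.weibull_cdf(durations, alpha, beta)
        k = rng.binomial(42, p, size=(200, 9))
        fits = psy.fit_weibull_batch(durations, k, np.full((200, 9), 42.0))
        assert fits["converged"].all()
        assert abs(np.median(fits["pse"]) - 1057.0) < 10.0

    def test_fitted_function_is_monotone_and_bounded(self, durations):
        rng = np.random.default_rng(5)
        data = make_counts(durations, 1100.0, 8.0, rng=rng, lapse=0.04)
        res = psy.WeibullPsychometric(data, lapse=0.04, penalized=True).fit()
        grid = np.linspace(700.0, 1400.0, 200)
        pred = res.predict(grid)
        assert np.all(np.diff(pred) >= 0.0)
        assert pred.min() >= 0.02 - 1e-12 and pred.max() <= 0.98 + 1e-12

    def test_all_identical_responses_direct_to_penalized_fit(self, durations):
        data = psy.PsychometricData(
            durations, np.zeros(9), np.full(9, 42.0)
        )
        with pytest.raises(ValueError, match="penalized"):
            psy.WeibullPsychometric(data)
        res = psy.WeibullPsychometric(data, penalized=True).fit()
        assert res.converged

    def test_too_few_levels_rejected(self):
        data = psy.PsychometricData(
            np.array([900.0, 1050.0, 1200.0]), np.array([5.0, 20.0, 40.0]),
            np.full(3, 42.0),
        )
        with pytest.raises(ValueError, match="4 duration levels"):
            psy.WeibullPsychometric(data)


@pytest.fixture(scope="module")
def fitted(durations):
    rng = np.random.default_rng(11)
    data = make_counts(durations, 1100.0, 8.0, rng=rng)
    return psy.fit_weibull(data)


class TestBootstrap:
    def test_same_seed_reproduces_intervals(self, fitted):
        c1 = fitted.bootstrap(n_boot=2000, seed=5)
        c2 = fitted.bootstrap(n_boot=2000, seed=5)
        assert c1.ci == c2.ci

    def test_interval_width_scales_like_root_n(self, durations):
        """Quadrupling trials per level (42 -> 168) shrinks the PSE CI width
        by a factor in [1.6, 2.4] (~sqrt(4) = 2)."""
        rng = np.random.default_rng(13)
        p = psy.weibull_cdf(durations, 1100.0, 8.0)
        widths = []
        for n_level in (42, 168):
            k = rng.binomial(n_level, p).astype(float)
            data = psy.PsychometricData(durations, k, np.full(9, float(n_level)))
            ci = psy.fit_weibull(data).bootstrap(n_boot=4000, seed=17)
            lo, hi = ci["pse"]
            widths.append(hi - lo)
        factor = widths[0] / widths[1]
        assert 1.6 <= factor <= 2.4

    def test_coverage_of_the_generating_pse(self, durations):
        """95% percentile intervals cover the generating PSE in 90-99% of
        200 simulated datasets."""
        rng = np.random.default_rng(19)
        pse_true = 1057.0
        alpha, beta = psy.alpha_for_pse(pse_true, 8.0), 8.0
        p = psy.weibull_cdf(durations, alpha, beta)
        hits = 0
        for i in range(200):
            k = rng.binomial(42, p).astype(float)
            data = psy.PsychometricData(durations, k, np.full(9, 42.0))
            try:
                res = psy.fit_weibull(data)
            except ValueError:
                res = psy.fit_weibull(data, penalized=True)
            lo, hi = res.bootstrap(n_boot=1000, seed=1000 + i)["pse"]
            hits += lo <= pse_true <= hi
        assert 0.90 <= hits / 200 <= 0.99

    def test_minimum_replicates_enforced(self, fitted):
        with pytest.raises(ValueError, match="1000"):
            fitted.bootstrap(n_boot=100)


class TestSummaries:
    def test_summary_table_contains_the_three_parameters(self, durations):
        res = psy.fit_weibull(make_counts(durations, 1100.0, 8.0))
        text = res.summary()
        for token in ("PSE", "threshold", "slope", "alpha", "beta"):
            assert token in text

    def test_summarize_fit_round_trip(self, durations):
        res = psy.fit_weibull(make_counts(durations, 1100.0, 8.0))
        s = psy.summarize_fit(res)
        assert s.pse_ms == pytest.approx(res.pse)
        assert s.threshold_ms > 0 and s.slope_per_ms > 0
        assert "0.5" in s.definitions["pse"] or "F^-1" in s.definitions["pse"]
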