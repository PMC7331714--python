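import numpy as np
import pandas as pd
import pytest

from serialdep import (
    BuildUpModel,
    ResamplingPlan,
    buildup_slope,
    derive_trials,
    guess_fraction_trend,
    mse_trend,
    sliding_buildup,
    slope_association,
    split_thirds,
    wrap_angle,
)


def session_with_folded_errors(folded, factory, **kwargs):
    """Session whose folded errors equal ``folded`` (theta_d kept at +30 deg)."""
    n = len(folded)
    d = np.radians(30)
    targets = wrap_angle(-d * np.arange(n))  # theta_d = +30 deg on every trial
    reports = wrap_angle(targets + np.asarray(folded))  # sign(theta_d) = +1
    df = factory(targets, reports, **kwargs)
    return derive_trials(df)


class TestSplitThirds:
    def test_nine_trials_split_evenly(self, trials_factory):
        t = trials_factory(np.zeros(9), np.zeros(9))
        parts = split_thirds(t)
        assert [len(p) for p in parts] == [3, 3, 3]

    def test_remainder_goes_to_earlier_thirds(self, trials_factory):
        t = trials_factory(np.zeros(10), np.zeros(10))
        assert [len(p) for p in split_thirds(t)] == [4, 3, 3]
        t11 = trials_factory(np.zeros(11), np.zeros(11))
        assert [len(p) for p in split_thirds(t11)] == [4, 4, 3]

    def test_concatenation_restores_session(self, trials_factory):
        t = trials_factory(np.arange(10, dtype=float) % (2 * np.pi), np.zeros(10))
        parts = split_thirds(t)
        pd.testing.assert_frame_equal(pd.concat(parts), t)

    def test_too_few_trials_rejected(self, trials_factory):
        with pytest.raises(ValueError, match="at least 3"):
            split_thirds(trials_factory([0.0, 1.0], [0.0, 1.0]))


class TestBuildupSlope:
    def test_exact_linear_trend_recovered(self, trials_factory):
        s = 1e-4
        folded = s * np.arange(50)
        sess = session_with_folded_errors(folded, trials_factory)
        assert buildup_slope(sess) == pytest.approx(s, rel=1e-9)

    def test_null_noise_slope_near_zero(self, trials_factory):
        rng = np.random.default_rng(0)
        folded = rng.normal(0.0, 0.05, size=400)
        sess = session_with_folded_errors(folded, trials_factory)
        n = 399  # usable trials (first has no reference)
        se = 0.05 / (np.sqrt(n) * np.std(np.arange(n)))
        assert abs(buildup_slope(sess)) < 3 * se

    def test_sessions_averaged_not_concatenated(self, trials_factory):
        a = session_with_folded_errors(1e-4 * np.arange(30), trials_factory, session="1")
        b = session_with_folded_errors(3e-4 * np.arange(30), trials_factory, session="2")
        subj = pd.concat([a, b], ignore_index=True)
        assert buildup_slope(subj) == pytest.approx(2e-4, rel=1e-9)

    def test_degenerate_session_rejected(self, trials_factory):
        sess = session_with_folded_errors([0.0, 0.01], trials_factory)
        # only one usable trial (the first lacks a reference)
        with pytest.raises(ValueError, match="usable"):
            buildup_slope(sess)


class TestSlidingBuildup:
    def test_constant_series_is_flat(self, trials_factory):
        sess = session_with_folded_errors(np.full(40, 0.02), trials_factory)
        series = sliding_buildup(sess, window_size=10)
        assert np.allclose(series.values, 0.02)

    def test_series_length(self, trials_factory):
        sess = session_with_folded_errors(np.zeros(40), trials_factory)
        series = sliding_buildup(sess, window_size=10)
        assert series.values.size == 39 - 10 + 1  # 39 usable trials

    def test_ramp_produces_increasing_series(self, trials_factory):
        sess = session_with_folded_errors(1e-3 * np.arange(60), trials_factory)
        series = sliding_buildup(sess, window_size=20)
        assert np.all(np.diff(series.values) > 0)

    def test_window_size_validation(self, trials_factory):
        sess = session_with_folded_errors(np.zeros(10), trials_factory)
        with pytest.raises(ValueError):
            sliding_buildup(sess, window_size=1)
        with pytest.raises(ValueError):
            sliding_buildup(sess, window_size=100)


class TestGuessFractionTrend:
    def test_extreme_two_window_case(self, trials_factory):
        # 40 trials, guesses exactly in trials 21-40
        targets = np.zeros(40)
        reports = np.concatenate([np.zeros(20), np.full(20, np.radians(170))])
        d = derive_trials(trials_factory(targets, wrap_angle(reports)))
        series, slope = guess_fraction_trend(d, window=20)
        assert list(series.values) == [0.0, 1.0]
        assert slope > 0

    def test_no_guesses_flat_zero(self, trials_factory):
        d = derive_trials(trials_factory(np.zeros(60), np.zeros(60)))
        series, slope = guess_fraction_trend(d, window=20)
        assert np.all(series.values == 0.0) and slope == 0.0

    def test_windows_are_independent_and_partial_dropped(self, trials_factory):
        d = derive_trials(trials_factory(np.zeros(50), np.zeros(50)))
        series, _ = guess_fraction_trend(d, window=20)
        assert series.values.size == 2  # trailing 10 trials dropped
        assert not series.overlapping

    def test_short_session_signalled(self, trials_factory):
        d = derive_trials(trials_factory(np.zeros(10), np.zeros(10)))
        with pytest.raises(ValueError, match="shorter"):
            guess_fraction_trend(d, window=20)

    def test_stationary_guess_rate_has_null_slope(self):
        from serialdep import SimConfig, simulate_experiment

        cfg = SimConfig(n_subjects=40, n_trials=200, guess_prob=0.1, seed=21)
        d = derive_trials(simulate_experiment(cfg))
        slopes = [
            guess_fraction_trend(g, window=20)[1]
            for _, g in d.groupby(["subject"], sort=False)
        ]
        t = np.mean(slopes) / (np.std(slopes, ddof=1) / np.sqrt(len(slopes)))
        assert abs(t) < 3


class TestMseTrend:
    def test_constant_error_magnitude_flat(self, trials_factory):
        folded = np.full(40, 0.05)
        sess = session_with_folded_errors(folded, trials_factory)
        series, slope = mse_trend(sess, window=20)
        assert np.allclose(series.values, 0.05**2)
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_shrinking_errors_give_negative_slope(self, trials_factory):
        folded = np.linspace(0.3, 0.01, 60)
        sess = session_with_folded_errors(folded, trials_factory)
        _, slope = mse_trend(sess, window=20)
        assert slope < 0


class TestSlopeAssociation:
    def test_exact_linear_relation(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        res = slope_association(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.r == pytest.approx(1.0)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            slope_association([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_needs_three_pairs(self):
        with pytest.raises(ValueError):
            slope_association([1.0, 2.0], [1.0, 2.0])

    def test_null_pvalue_is_calibrated(self):
        """Independent slopes: regression p approximately uniform."""
        rng = np.random.default_rng(6)
        ps = [
            slope_association(rng.normal(size=20), rng.normal(size=20)).pvalue
            for _ in range(300)
        ]
        from scipy import stats as sps

        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestBuildUpModel:
    def test_fit_on_ramped_simulation(self):
        from serialdep import DoGParams, SimConfig, simulate_experiment

        cfg = SimConfig(n_subjects=25, n_trials=300, seed=13,
                        a_schedule="ramp", a_start=0.0, a_end=0.09)
        model = BuildUpModel(simulate_experiment(cfg))
        res = model.fit(ResamplingPlan(n_boot=500, seed=3))
        assert res.pooled.estimate > 0
        assert res.pooled.ci_low > 0
        assert "build-up" in res.summary().lower() or "slope" in res.summary()

    def test_thirds_comparison_identical_groups_null(self, trials_factory):
        rng = np.random.default_rng(8)
        targets = rng.uniform(0, 2 * np.pi, 120)
        reports = wrap_angle(targets + rng.normal(0, 0.05, 120))
        model = BuildUpModel(trials_factory(targets, reports))
        curves, perm = model.thirds_comparison(
            ("first", "last"), ResamplingPlan(n_boot=100, n_perm=200, seed=4))
        assert set(curves) == {"first", "last"}
        valid = np.isfinite(perm.pvalues)
        # exchangeable thirds: no systematic differences
        assert np.nanmean(perm.pvalues[valid] < 0.05) < 0.3
        assert perm.metadata["multiple_comparison_correction"].startswith("none")

    def test_thirds_validation(self, null_sim):
        model = BuildUpModel(null_sim.iloc[:600])
        with pytest.raises(ValueError, match="thirds"):
            model.thirds_comparison(("first", "second"))

    def test_control_association_reports_pooled_and_per_experiment(self):
        from serialdep import SimConfig, simulate_experiment

        cfg = SimConfig(n_subjects=12, n_trials=120, guess_prob=0.1, seed=17)
        model = BuildUpModel(simulate_experiment(cfg))
        out = model.control_association(
            "guess", window=20, plan=ResamplingPlan(n_boot=200, seed=5))
        assert "pooled" in out and "per_experiment" in out
        assert out["pooled"]["n"] == 12
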