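import numpy as np
import pandas as pd
import pytest

from serialdep import (
    NoUsableTrialsError,
    ResamplingPlan,
    SerialBiasModel,
    derive_trials,
    mean_folded_error,
    serial_bias_curve,
    wrap_angle,
)


def trials_with_distances(distances, errors, factory):
    """Build a session whose theta_d sequence and per-trial errors are prescribed.

    theta_d(k) = wrap(target_{k-1} - target_k), so targets chain as
    t_k = t_{k-1} - theta_d(k).  ``errors`` has one entry per trial
    (the first trial's error is irrelevant to folding).
    """
    targets = [0.0]
    for d in distances:
        targets.append(wrap_angle(targets[-1] - d))
    targets = np.array(targets)
    reports = wrap_angle(targets + np.asarray(errors))
    return factory(targets, reports)


PLAN = ResamplingPlan(n_boot=300, seed=0)


class TestMeanFoldedError:
    def test_symmetric_pair_gives_zero(self, trials_factory):
        d = np.radians(30)
        # constant +2 deg error; theta_d flips sign, so folding gives {+2, -2}
        t = trials_with_distances([d, -d], [0.0, np.radians(2), np.radians(2)],
                                  trials_factory)
        res = mean_folded_error(derive_trials(t), plan=PLAN)
        # folded errors are {+2, -2} deg
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_additive_bias_cancels_exactly(self, trials_factory):
        """Constant error + sign-balanced theta_d -> statistic exactly 0."""
        rng = np.random.default_rng(4)
        mags = rng.uniform(0.05, np.pi / 2 - 0.05, size=25)
        dists = np.concatenate([mags, -mags])
        c = 0.123
        t = trials_with_distances(dists, np.full(dists.size + 1, c), trials_factory)
        res = mean_folded_error(derive_trials(t), plan=PLAN)
        assert res.estimate == pytest.approx(0.0, abs=1e-12)

    def test_additive_shift_invariance(self, trials_factory):
        """Adding a constant to all errors leaves the statistic unchanged."""
        rng = np.random.default_rng(5)
        mags = rng.uniform(0.05, np.pi / 2 - 0.05, size=20)
        dists = np.concatenate([mags, -mags])
        base_err = rng.normal(0, 0.05, size=dists.size + 1)
        t0 = trials_with_distances(dists, base_err, trials_factory)
        t1 = trials_with_distances(dists, base_err + 0.2, trials_factory)
        r0 = mean_folded_error(derive_trials(t0), plan=PLAN)
        r1 = mean_folded_error(derive_trials(t1), plan=PLAN)
        assert r1.estimate == pytest.approx(r0.estimate, abs=1e-10)

    def test_max_distance_restricts_trials(self, trials_factory):
        t = trials_with_distances(
            [np.radians(30), np.radians(170), np.radians(-30)],
            np.radians([0.0, 1.0, 5.0, 1.0]), trials_factory)
        res = mean_folded_error(derive_trials(t), max_distance=np.pi / 2, plan=PLAN)
        assert res.n == 2  # the 170-deg trial is outside the cut

    def test_no_usable_trials_signalled(self, trials_factory):
        t = trials_factory([1.0], [1.1])  # single trial: no previous reference
        with pytest.raises(NoUsableTrialsError):
            mean_folded_error(derive_trials(t), plan=PLAN)

    def test_ci_is_seed_deterministic(self, attract_derived):
        r1 = mean_folded_error(attract_derived, plan=ResamplingPlan(n_boot=200, seed=9))
        r2 = mean_folded_error(attract_derived, plan=ResamplingPlan(n_boot=200, seed=9))
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)


class TestSerialBiasCurve:
    def test_window_mean_of_constant(self, trials_factory):
        dists = np.radians(np.full(30, 20.0))
        t = trials_with_distances(dists, np.full(31, 0.05), trials_factory)
        curve = serial_bias_curve(derive_trials(t), plan=PLAN)
        filled = curve.n_trials > 0
        assert np.allclose(curve.mean_error[filled], 0.05)

    def test_empty_windows_are_missing_not_zero(self, trials_factory):
        dists = np.radians([20.0, -20.0, 25.0])
        t = trials_with_distances(dists, np.zeros(4), trials_factory)
        curve = serial_bias_curve(derive_trials(t), plan=PLAN)
        far = curve.centers > np.radians(25) + curve.window_size / 2
        assert np.all(np.isnan(curve.mean_error[far]))
        assert np.all(curve.n_trials[far] == 0)

    def test_default_windowing(self, attract_derived):
        curve = serial_bias_curve(attract_derived, plan=PLAN)
        assert curve.window_size == pytest.approx(np.pi / 2)
        assert curve.step == pytest.approx(np.pi / 30)
        assert curve.centers.size == 31  # multiples of pi/30 over [0, pi]
        assert curve.centers[0] == 0.0 and curve.centers[-1] == pytest.approx(np.pi)

    def test_window_means_recomputable_from_members(self, attract_derived):
        curve = serial_bias_curve(attract_derived, plan=PLAN)
        use = attract_derived[attract_derived.has_reference]
        x = np.abs(use["prev_distance"].to_numpy())
        y = use["folded_error"].to_numpy()
        for i in (0, 10, 20, 30):
            members = np.abs(x - curve.centers[i]) <= curve.window_size / 2 + 1e-12
            if members.any():
                assert curve.mean_error[i] == pytest.approx(y[members].mean())
                assert curve.n_trials[i] == members.sum()

    def test_fold_unfold_consistency(self, attract_derived):
        """On interior windows the folded curve equals the count-weighted
        combination of the unfolded curve at +d and its negation at -d."""
        folded = serial_bias_curve(attract_derived, folded=True, plan=PLAN)
        unfolded = serial_bias_curve(attract_derived, folded=False, plan=PLAN)
        for i, c in enumerate(folded.centers):
            if not (np.pi / 4 + 1e-9 < c < 3 * np.pi / 4 - 1e-9):
                continue
            j_pos = np.argmin(np.abs(unfolded.centers - c))
            j_neg = np.argmin(np.abs(unfolded.centers + c))
            n_pos, n_neg = unfolded.n_trials[j_pos], unfolded.n_trials[j_neg]
            expected = (
                n_pos * unfolded.mean_error[j_pos] - n_neg * unfolded.mean_error[j_neg]
            ) / (n_pos + n_neg)
            assert folded.mean_error[i] == pytest.approx(expected, abs=1e-10)
            assert folded.n_trials[i] == n_pos + n_neg

    def test_attraction_visible_at_small_distances(self, attract_derived):
        curve = serial_bias_curve(attract_derived, plan=ResamplingPlan(n_boot=400, seed=1))
        small = curve.centers <= np.pi / 2
        assert np.nanmean(curve.mean_error[small]) > 0
        assert (curve.ci_low[small] > 0).mean() > 0.5


class TestSerialBiasModel:
    def test_fit_summary_and_roundtrip(self, attract_sim):
        model = SerialBiasModel(attract_sim)
        res = model.fit(ResamplingPlan(n_boot=300, seed=2))
        text = res.summary()
        assert "mean folded error" in text
        assert res.mean_folded.estimate > 0
        assert res.pvalue_bootstrap < 0.05
        d = res.to_dict()
        assert d["n_subjects"] == attract_sim["subject"].nunique()
        assert d["mean_folded_error"]["estimate_deg"] == pytest.approx(
            res.mean_folded.estimate_deg)

    def test_guess_exclusion_wiring(self, trials_factory):
        targets = np.linspace(0.1, 2.0, 6)
        reports = targets.copy()
        reports[3] = wrap_angle(targets[3] + np.radians(170))
        model = SerialBiasModel(trials_factory(targets, reports))
        assert len(model.excluded) == 1
        model_keep = SerialBiasModel(trials_factory(targets, reports), drop_guesses=False)
        assert len(model_keep.excluded) == 0
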