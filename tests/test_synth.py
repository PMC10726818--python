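"""Synthetic generator: behaviour, neural profiles, BOLD synthesis."""

import numpy as np
import pandas as pd
import pytest

from gradreveal.synth import (
    GroundTruth,
    ParadigmConfig,
    ProfileKind,
    _draw_itis,
    apply_habituation,
    hrf_kernel,
    neural_profile,
    simulate_behavior,
    simulate_subject,
    synthesize_bold,
)


class TestSimulateBehavior:
    def test_slower_drift_gives_strictly_longer_rts_without_noise(self):
        gt = GroundTruth(
            drift_rate={"neutral": 0.10, "high": 0.06},
            threshold={"neutral": 1.0, "high": 1.0},
            rt_noise_sd=0.0,
        )
        ev = simulate_behavior(gt, ParadigmConfig(), np.random.default_rng(0))
        high = ev.loc[ev.trial_type == "high", "response_time"]
        neutral = ev.loc[ev.trial_type == "neutral", "response_time"]
        assert high.min() > neutral.max()

    def test_same_seed_reproduces_table_bit_identically(self):
        gt = GroundTruth(seed=42)
        a = simulate_behavior(gt, ParadigmConfig())
        b = simulate_behavior(gt, ParadigmConfig())
        pd.testing.assert_frame_equal(a, b)

    def test_itis_are_uniform_over_the_jitter_set(self, rng):
        itis = _draw_itis(rng, 10_000, (6.0, 8.0, 10.0))
        values, counts = np.unique(itis, return_counts=True)
        assert set(values) == {6.0, 8.0, 10.0}
        assert np.all(np.abs(counts / 10_000 - 1 / 3) < 0.02)

    def test_timing_conservation_within_runs(self):
        gt = GroundTruth(seed=7)
        par = ParadigmConfig()
        ev = simulate_behavior(gt, par)
        # onset + rt + post-decision + minimum ITI fits inside every run
        assert (
            ev.onset + ev.response_time + par.post_decision_duration + min(par.iti_choices)
            <= par.run_duration + 1e-9
        ).all()
        assert ev.run.max() <= par.n_runs

    def test_mean_rt_direction_matches_distractor_effect(self):
        # slower drift + higher threshold for high salience -> longer RTs
        hits = 0
        for seed in range(20):
            ev = simulate_behavior(GroundTruth(seed=seed), ParadigmConfig())
            means = ev.groupby("trial_type")["response_time"].mean()
            hits += means["high"] > means["neutral"]
        assert hits == 20

    def test_rejects_mean_rt_reaching_reveal_duration(self):
        gt = GroundTruth(
            drift_rate={"neutral": 0.03, "high": 0.03},
            threshold={"neutral": 1.0, "high": 1.0},
        )
        with pytest.raises(ValueError, match="reveal"):
            simulate_behavior(gt, ParadigmConfig())

    def test_rejects_negative_rt_noise(self):
        with pytest.raises(ValueError, match="rt_noise_sd"):
            GroundTruth(rt_noise_sd=-1.0)


class TestGroundTruthValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"drift_rate": {"neutral": -0.1, "high": 0.1}, "threshold": {"neutral": 1, "high": 1}},
            {"threshold": {"neutral": 0.0, "high": 1.0}, "drift_rate": {"neutral": 0.1, "high": 0.1}},
            {"accuracy_prob": 0.0},
            {"accuracy_prob": 1.5},
            {"ar1_coef": 1.0},
            {"habituation_factor": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GroundTruth(**kwargs)


class TestNeuralProfile:
    def test_accumulator_linear_ramp_hits_midpoint_and_threshold(self):
        gt = GroundTruth(threshold={"neutral": 1.0, "high": 1.0})
        grid = np.arange(0.0, 21.0, 1.0)
        out = neural_profile(ProfileKind.ACCUMULATOR, gt, rt=10.0, grid=grid)
        assert out[5] == pytest.approx(0.5)
        assert out[10] == pytest.approx(1.0)
        assert np.argmax(out) == 10

    def test_accumulator_peak_equals_threshold_on_tr_grid(self):
        gt = GroundTruth(threshold={"neutral": 1.3, "high": 1.3})
        grid = np.arange(0.0, 24.0, 0.42)
        out = neural_profile(ProfileKind.ACCUMULATOR, gt, rt=12.3, grid=grid)
        assert out.max() == pytest.approx(1.3, abs=0)
        assert grid[np.argmax(out)] == pytest.approx(12.3, abs=0.21)

    def test_step_is_zero_before_decision_and_constant_after(self):
        gt = GroundTruth(threshold={"neutral": 0.8, "high": 0.8})
        grid = np.array([11.9, 12.0, 12.1, 21.9, 22.1])
        out = neural_profile(ProfileKind.STEP, gt, rt=12.0, grid=grid)
        assert out[0] == 0.0
        assert out[1] == pytest.approx(0.8)
        assert out[2] == pytest.approx(0.8)
        assert out[4] == 0.0

    def test_mod_bump_integrates_to_amplitude_times_width_constant(self):
        gt = GroundTruth(threshold={"neutral": 1.0, "high": 1.0}, mod_width=0.75)
        grid = np.arange(0.0, 25.0, 0.01)
        out = neural_profile(ProfileKind.MOMENT_OF_DECISION, gt, rt=12.0, grid=grid)
        integral = np.trapezoid(out, grid)
        expected = 1.0 * gt.mod_width * np.sqrt(2 * np.pi)
        assert integral == pytest.approx(expected, rel=0.01)

    def test_rt_outside_grid_rejected(self):
        gt = GroundTruth()
        with pytest.raises(ValueError, match="outside"):
            neural_profile(ProfileKind.SENSORY, gt, rt=30.0, grid=np.arange(0.0, 20.0, 1.0))


class TestSynthesizeBold:
    def _zero_noise_truth(self):
        return GroundTruth(
            noise_sd=0.0, drift_amplitude=0.0, global_amplitude=0.0, rt_noise_sd=0.0
        )

    def _one_trial_events(self, rt=10.0):
        return pd.DataFrame(
            {
                "onset": [0.0],
                "duration": [rt + 10.0],
                "trial_type": ["neutral"],
                "response_time": [rt],
                "correct": [1],
                "run": [1],
            }
        )

    def test_zero_input_zero_noise_gives_zero_output(self):
        gt = self._zero_noise_truth()
        par = ParadigmConfig(n_runs=1)
        ev = self._one_trial_events()
        profiles = {"roi": [np.zeros(60)]}
        series = synthesize_bold(profiles, ev, gt, par, np.random.default_rng(0))
        assert np.all(series.values == 0.0)

    def test_impulse_response_peaks_3_to_6_seconds_after_onset(self):
        gt = self._zero_noise_truth()
        par = ParadigmConfig(n_runs=1)
        ev = self._one_trial_events()
        impulse = np.zeros(60)
        impulse[0] = 1.0
        series = synthesize_bold({"roi": [impulse]}, ev, gt, par, np.random.default_rng(0))
        t_max = np.argmax(series.values[:, 0]) * par.tr
        assert 3.0 <= t_max <= 6.0

    def test_convolution_matches_direct_discrete_sum(self):
        # brute-force O(n*k) convolution oracle
        gt = self._zero_noise_truth()
        par = ParadigmConfig(n_runs=1)
        ev = self._one_trial_events()
        rng = np.random.default_rng(5)
        prof = rng.standard_normal(50) ** 2  # non-negative arbitrary signal
        series = synthesize_bold({"roi": [prof]}, ev, gt, par, np.random.default_rng(0))
        kernel = hrf_kernel(par.tr)
        n = par.samples_per_run
        neural = np.zeros(n)
        neural[: len(prof)] = prof
        direct = np.zeros(n)
        for i in range(n):
            for k in range(len(kernel)):
                if i - k >= 0:
                    direct[i] += kernel[k] * neural[i - k]
        assert np.max(np.abs(series.values[:, 0] - direct)) < 1e-10

    def test_overlapping_trials_rejected(self):
        gt = self._zero_noise_truth()
        par = ParadigmConfig(n_runs=1)
        ev = pd.DataFrame(
            {
                "onset": [0.0, 5.0],
                "duration": [20.0, 20.0],
                "trial_type": ["neutral", "high"],
                "response_time": [10.0, 10.0],
                "correct": [1, 1],
                "run": [1, 1],
            }
        )
        with pytest.raises(ValueError, match="overlap"):
            synthesize_bold({"roi": [np.ones(10), np.ones(10)]}, ev, gt, par)

    def test_nan_profile_rejected(self):
        gt = self._zero_noise_truth()
        par = ParadigmConfig(n_runs=1)
        bad = np.ones(10)
        bad[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            synthesize_bold({"roi": [bad]}, self._one_trial_events(), gt, par)


class TestHrfKernel:
    def test_unit_dc_gain_and_positive_peak(self):
        k = hrf_kernel(0.42)
        assert k.sum() == pytest.approx(1.0)
        assert k.max() > 0
        assert 3.0 <= np.argmax(k) * 0.42 <= 6.0


class TestHabituation:
    def _events(self, runs):
        n = len(runs)
        return pd.DataFrame(
            {
                "onset": np.zeros(n),
                "duration": np.full(n, 20.0),
                "trial_type": ["high"] * n,
                "response_time": np.full(n, 10.0),
                "correct": np.ones(n, dtype=int),
                "run": runs,
            }
        )

    def test_factor_one_is_identity(self):
        ev = self._events([1, 4, 7])
        amps = np.array([1.0, 1.0, 1.0])
        out = apply_habituation(amps, ev, 1.0)
        assert np.array_equal(out, amps)

    def test_geometric_decay_across_blocks(self):
        ev = self._events([1, 4, 7])  # blocks 1, 2, 3
        out = apply_habituation(np.ones(3), ev, 0.5)
        assert np.allclose(out, [1.0, 0.5, 0.25])

    def test_non_positive_factor_rejected(self):
        ev = self._events([1])
        with pytest.raises(ValueError):
            apply_habituation(np.ones(1), ev, 0.0)

    def test_more_than_nine_runs_rejected(self):
        ev = self._events([10])
        with pytest.raises(ValueError, match="9 runs"):
            apply_habituation(np.ones(1), ev, 0.5)


class TestSimulateSubject:
    def test_same_seed_bit_identical_series(self, default_truth, small_paradigm):
        kinds = {"acc": ProfileKind.ACCUMULATOR}
        a = simulate_subject(default_truth, small_paradigm, kinds, np.random.default_rng(3))
        b = simulate_subject(default_truth, small_paradigm, kinds, np.random.default_rng(3))
        pd.testing.assert_frame_equal(a.events, b.events)
        assert np.array_equal(a.series.values, b.series.values)

    def test_series_shape_matches_paradigm(self, simulated_subject, small_paradigm):
        s = simulated_subject.series
        assert s.n_samples == small_paradigm.samples_per_run * s.run_index.max()
        assert s.n_rois == 2
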