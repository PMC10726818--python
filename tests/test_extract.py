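"""Extraction: nuisance regression, correct-trial filtering, epoching."""

import numpy as np
import pandas as pd
import pytest

from gradreveal.containers import RoiTimeSeries
from gradreveal.extract import epoch_trials, filter_correct, regress_confounds


def _series(values, tr=0.42, runs=1):
    values = np.atleast_2d(values.T).T if values.ndim == 1 else values
    n = values.shape[0]
    per = n // runs
    run_index = np.repeat(np.arange(1, runs + 1), per)
    names = tuple(f"roi{j}" for j in range(values.shape[1]))
    return RoiTimeSeries(values=values, roi_names=names, tr=tr, run_index=run_index)


def _events(rows):
    return pd.DataFrame(
        rows, columns=["onset", "duration", "trial_type", "response_time", "correct", "run"]
    )


class TestRegressConfounds:
    def test_orthogonal_confound_leaves_detrended_zscored_input(self, rng):
        n = 400
        t = np.arange(n)
        y = np.sin(2 * np.pi * 5 * t / n)
        conf = pd.DataFrame({"c": np.cos(2 * np.pi * 5 * t / n)})  # orthogonal to y
        series = _series(y[:, None])
        out = regress_confounds(series, conf)
        # oracle: detrend + z-score only
        ref = regress_confounds(series, None)
        assert np.max(np.abs(out.values - ref.values)) < 1e-10

    def test_roi_equal_to_confound_is_flagged_degenerate(self, rng):
        y = rng.standard_normal(200)
        series = _series(y[:, None])
        out = regress_confounds(series, pd.DataFrame({"c": y}))
        assert out.degenerate_rois == ("roi0",)
        assert np.allclose(out.values, 0.0)

    def test_residuals_match_normal_equations_on_toy_matrix(self, rng):
        n = 20
        X = rng.standard_normal((n, 3))
        Y = rng.standard_normal((n, 2))
        series = _series(Y)
        out = regress_confounds(series, pd.DataFrame(X, columns=list("abc")))
        # oracle: explicit normal equations on the standardized design
        Xs = (X - X.mean(0)) / X.std(0)
        Xd = np.column_stack([np.ones(n), Xs])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ Y)
        resid = Y - Xd @ beta
        # then linear detrend + z-score, as the pipeline does
        t = np.arange(n, dtype=float)
        td = np.column_stack([np.ones(n), t])
        resid = resid - td @ np.linalg.solve(td.T @ td, td.T @ resid)
        resid = (resid - resid.mean(0)) / resid.std(0)
        assert np.max(np.abs(out.values - resid)) < 1e-8

    def test_rank_deficient_confounds_warn_and_still_solve(self, rng, caplog):
        y = rng.standard_normal(100)
        c = rng.standard_normal(100)
        conf = pd.DataFrame({"a": c, "b": c})  # duplicated column
        with caplog.at_level("WARNING", logger="gradreveal.extract"):
            out = regress_confounds(_series(y[:, None]), conf)
        assert "rank deficient" in caplog.text
        assert np.isfinite(out.values).all()

    def test_constant_roi_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regress_confounds(_series(np.ones((50, 1))), None)

    def test_standardization_invariant_per_run(self, rng):
        y = rng.standard_normal((300, 2)) + 5.0
        series = _series(y, runs=3)
        out = regress_confounds(series, None)
        for run in out.runs:
            sl = out.run_slice(run)
            assert np.all(np.abs(out.values[sl].mean(axis=0)) < 1e-8)
            assert np.all(np.abs(out.values[sl].std(axis=0) - 1) < 1e-6)


class TestFilterCorrect:
    def test_removes_incorrect_trials(self):
        ev = _events(
            [(i * 30.0, 20.0, "neutral" if i % 2 else "high", 10.0, int(i not in (2, 5)), 1)
             for i in range(10)]
        )
        out = filter_correct(ev)
        assert len(out) == 8
        assert list(out.index) == [i for i in range(10) if i not in (2, 5)]

    def test_all_correct_is_identity(self):
        ev = _events([(0.0, 20.0, "high", 10.0, 1, 1), (30.0, 20.0, "neutral", 9.0, 1, 1)])
        pd.testing.assert_frame_equal(filter_correct(ev), ev)

    def test_missing_response_time_removed(self):
        ev = _events(
            [
                (0.0, 20.0, "high", 10.0, 1, 1),
                (30.0, 20.0, "high", np.nan, 1, 1),
                (60.0, 20.0, "neutral", 9.0, 1, 1),
            ]
        )
        out = filter_correct(ev)
        assert len(out) == 2
        assert out["response_time"].notna().all()

    def test_condition_losing_all_trials_raises(self):
        ev = _events([(0.0, 20.0, "high", 10.0, 0, 1), (30.0, 20.0, "neutral", 9.0, 1, 1)])
        with pytest.raises(ValueError, match="high"):
            filter_correct(ev)


class TestEpochTrials:
    TR = 0.42

    def test_shift_is_twelve_samples_and_post_is_twentyfour(self):
        n = 400
        series = _series(np.arange(n, dtype=float)[:, None], tr=self.TR)
        ev = _events([(10.0, 22.0, "neutral", 12.0, 1, 1)])
        (ep,) = epoch_trials(series, ev, shift_s=5.0)
        i_on = round(10.0 / self.TR) + 12
        i_resp = round(22.0 / self.TR) + 12
        assert ep.pre[0, 0] == i_on
        assert ep.pre[-1, 0] == i_resp - 1
        assert ep.post.shape[0] == 24
        assert ep.post[0, 0] == i_resp

    def test_epoch_contents_equal_index_identity_oracle(self):
        # sample value == global sample index; epochs must be exact ranges
        n_per = 500
        vals = np.arange(2 * n_per, dtype=float)[:, None]
        series = _series(vals, tr=self.TR, runs=2)
        ev = _events(
            [
                (5.0, 18.0, "high", 8.0, 1, 1),
                (60.0, 21.0, "neutral", 11.0, 1, 2),
            ]
        )
        eps = epoch_trials(series, ev, shift_s=5.0)
        k = 12
        for ep, (onset, rt, run) in zip(eps, [(5.0, 8.0, 1), (60.0, 11.0, 2)]):
            start = (run - 1) * n_per
            i_on = start + int(np.floor(onset / self.TR + 0.5)) + k
            i_resp = start + int(np.floor((onset + rt) / self.TR + 0.5)) + k
            assert np.array_equal(ep.pre[:, 0], np.arange(i_on, i_resp))
            assert np.array_equal(ep.post[:, 0], np.arange(i_resp, i_resp + 24))

    def test_trial_overrunning_run_end_is_dropped(self):
        series = _series(np.random.default_rng(0).standard_normal((100, 1)), tr=self.TR)
        # run is 42 s long; trial response at 35 s leaves no room for post+shift
        ev = _events([(25.0, 20.0, "neutral", 10.0, 1, 1), (0.0, 18.0, "high", 8.0, 1, 1)])
        eps = epoch_trials(series, ev, shift_s=5.0)
        assert [e.condition for e in eps] == ["high"]

    def test_too_short_rt_is_dropped(self):
        series = _series(np.random.default_rng(0).standard_normal((400, 1)), tr=self.TR)
        ev = _events([(10.0, 10.5, "high", 0.5, 1, 1), (40.0, 20.0, "neutral", 10.0, 1, 1)])
        eps = epoch_trials(series, ev, shift_s=5.0)
        assert [e.condition for e in eps] == ["neutral"]

    def test_epoch_count_equals_surviving_trials(self, simulated_subject):
        ev = filter_correct(simulated_subject.events)
        eps = epoch_trials(simulated_subject.series, ev, shift_s=5.0)
        assert len(eps) <= len(ev)
        assert {e.condition for e in eps} <= {"high", "neutral"}

    def test_shift_equivariance(self, rng):
        """Shifting the series by k samples while reducing shift_s by k*tr
        yields identical epochs."""
        n = 600
        vals = rng.standard_normal((n, 1))
        ev = _events([(20.0, 22.0, "neutral", 12.0, 1, 1)])
        series = _series(vals, tr=self.TR)
        (a,) = epoch_trials(series, ev, shift_s=5.0)
        k = 3
        shifted = np.roll(vals, -k, axis=0)  # advance the series by k samples
        series_b = _series(shifted, tr=self.TR)
        (b,) = epoch_trials(series_b, ev, shift_s=5.0 - k * self.TR)
        assert np.array_equal(a.pre, b.pre)
        assert np.array_equal(a.post, b.post)
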