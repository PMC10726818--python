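"""Common-grid interpolation and FIR estimation of condition profiles.

Self-paced trials have pre-decision segments of different lengths.  To
compare them, each trial's pre-decision residuals are linearly
resampled onto a common grid whose length is set by the condition's
mean correct response time; the 10-s post-decision segment is appended
without resampling; and the trial is zero-locked so its first grid value
is exactly zero.  A finite impulse response (FIR) model — one indicator
regressor per grid time bin, solved by ordinary least squares — then
summarises the trials of each subject x ROI x condition into a single
coefficient series.  For this stacked, non-overlapping design the FIR
solution coincides with the pointwise trial mean, which serves as the
correctness oracle for the estimator.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    ConditionProfile,
    InterpolatedTrial,
    TrialEpoch,
    round_half_up,
)

__all__ = ["condition_grid_length", "interpolate_trial", "fir_fit", "fit_condition_profiles"]


def condition_grid_length(events: pd.DataFrame, condition: str, tr: float) -> int:
    """Common pre-decision grid length (samples) for one condition.

    ``round(mean correct RT of the condition / tr)``; the event table
    must already be filtered to correct trials.
    """
    rts = events.loc[events["trial_type"] == condition, "response_time"]
    if rts.empty:
        raise ValueError(f"no trials for condition {condition!r}")
    return round_half_up(float(rts.mean()) / tr)


def interpolate_trial(epoch: TrialEpoch, target_pre_len: int) -> InterpolatedTrial:
    """Conform one epoch to the condition grid and zero-lock it.

    The pre-decision segment is linearly resampled onto
    ``target_pre_len`` equally spaced points whose first and last points
    coincide with the original first and last pre-decision samples; the
    post-decision segment is appended unchanged; the whole vector is
    then shifted so the first grid value is exactly zero.
    """
    if target_pre_len < 2:
        raise ValueError("target_pre_len must be at least 2")
    if np.isnan(epoch.pre).any() or np.isnan(epoch.post).any():
        raise ValueError("NaN in epoch")
    n_pre, n_rois = epoch.pre.shape
    src = np.linspace(0.0, 1.0, n_pre)
    dst = np.linspace(0.0, 1.0, target_pre_len)
    pre = np.empty((target_pre_len, n_rois))
    for j in range(n_rois):
        pre[:, j] = np.interp(dst, src, epoch.pre[:, j])
    values = np.vstack([pre, epoch.post])
    zero_ref = values[0].copy()
    values = values - zero_ref
    return InterpolatedTrial(
        trial_id=epoch.trial_id,
        condition=epoch.condition,
        values=values,
        pre_len=target_pre_len,
        zero_ref=zero_ref,
        roi_names=epoch.roi_names,
        tr=epoch.tr,
        run=epoch.run,
        rt=epoch.rt,
        subject=epoch.subject,
    )


def fir_fit(
    trials: Sequence[InterpolatedTrial],
    condition: str,
    mean_rt: float,
    subject: str = "",
) -> dict[str, ConditionProfile]:
    """Estimate FIR coefficient series for one condition, per ROI.

    Builds the stacked design with one indicator regressor per grid time
    bin across all trials of ``condition`` and solves it by ordinary
    least squares (``numpy.linalg.lstsq``).  Returns one
    :class:`ConditionProfile` per ROI.
    """
    sel = [t for t in trials if t.condition == condition]
    if not sel:
        raise ValueError(f"no trials for condition {condition!r}")
    lengths = {t.values.shape[0] for t in sel}
    if len(lengths) != 1:
        raise ValueError(f"grid-length mismatch across trials: {sorted(lengths)}")
    L = lengths.pop()
    pre_lens = {t.pre_len for t in sel}
    if len(pre_lens) != 1:
        raise ValueError("trials mix different pre-decision grid lengths")
    roi_names = sel[0].roi_names
    tr = sel[0].tr
    n = len(sel)
    # Stacked indicator design: n copies of the LxL identity.
    X = np.tile(np.eye(L), (n, 1))
    Y = np.concatenate([t.values for t in sel], axis=0)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return {
        roi: ConditionProfile(
            subject=subject or sel[0].subject,
            roi=roi,
            condition=condition,
            coef=coef[:, j],
            n_trials=n,
            mean_rt=mean_rt,
            tr=tr,
            pre_len=sel[0].pre_len,
        )
        for j, roi in enumerate(roi_names)
    }


def fit_condition_profiles(
    epochs: Sequence[TrialEpoch],
    events: pd.DataFrame,
    tr: float,
    conditions: Sequence[str] | None = None,
    grid_lengths: dict[str, int] | None = None,
    subject: str = "",
) -> tuple[dict[tuple[str, str], ConditionProfile], dict[str, list[InterpolatedTrial]]]:
    """Interpolate epochs per condition and fit FIR profiles.

    ``grid_lengths`` overrides the per-subject condition grid (e.g. with
    a group-level grid); by default the grid length is computed from the
    subject's own mean correct response times.  Returns the profiles
    keyed by ``(roi, condition)`` together with the interpolated trials
    per condition (used downstream for trial-level peak metrics).
    """
    if conditions is None:
        conditions = list(dict.fromkeys(e.condition for e in epochs))
    profiles: dict[tuple[str, str], ConditionProfile] = {}
    trials_by_cond: dict[str, list[InterpolatedTrial]] = {}
    for cond in conditions:
        cond_epochs = [e for e in epochs if e.condition == cond]
        if not cond_epochs:
            continue
        if grid_lengths and cond in grid_lengths:
            pre_len = grid_lengths[cond]
        else:
            pre_len = condition_grid_length(events, cond, tr)
        trials = [interpolate_trial(e, pre_len) for e in cond_epochs]
        trials_by_cond[cond] = trials
        mean_rt = float(
            events.loc[events["trial_type"] == cond, "response_time"].mean()
        )
        for roi, prof in fir_fit(trials, cond, mean_rt, subject=subject).items():
            profiles[(roi, cond)] = prof
    return profiles, trials_by_cond
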