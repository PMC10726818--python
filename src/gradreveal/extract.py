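"""From raw ROI series to per-trial residual epochs.

Stages: nuisance regression against a confound table (global signal,
CSF/WM, cosine drift, non-steady-state spikes, with derivative and
quadratic expansions), per-run linear detrending and z-scoring,
filtering to correct trials, a fixed hemodynamic shift, and epoching
each trial into a variable-length pre-decision segment and a fixed 10-s
post-decision segment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .containers import RoiTimeSeries, TrialEpoch, round_half_up, validate_events

__all__ = ["regress_confounds", "filter_correct", "epoch_trials"]

logger = logging.getLogger(__name__)

#: Residuals whose pre-standardization spread falls below this are treated
#: as degenerate (the ROI was fully explained by the confounds).
DEGENERATE_SD = 1e-8


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    """Z-score confound columns; all-constant columns become zeros."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe


def regress_confounds(
    series: RoiTimeSeries,
    confounds: pd.DataFrame | None = None,
) -> RoiTimeSeries:
    """Nuisance-regress, detrend and standardize an ROI series.

    Per run and ROI: the confound columns (standardized, plus an
    intercept) are fit by least squares and their contribution removed;
    the residual is linearly detrended and then z-scored to mean 0 /
    sd 1.  A rank-deficient confound matrix is handled by the
    minimum-norm least-squares solution and logged.  ROIs whose
    residuals are numerically constant are flagged in
    ``degenerate_rois`` (their standardized values are set to zero
    rather than amplified noise).

    Raises ``ValueError`` if an input ROI column is constant within a run.
    """
    if confounds is not None and len(confounds) != series.n_samples:
        raise ValueError(
            f"confound rows ({len(confounds)}) do not match series samples "
            f"({series.n_samples})"
        )
    out = np.empty_like(series.values)
    degenerate: set[str] = set()
    for run in series.runs:
        sl = series.run_slice(run)
        Y = series.values[sl]
        sds = Y.std(axis=0)
        if np.any(sds == 0):
            bad = [series.roi_names[j] for j in np.flatnonzero(sds == 0)]
            raise ValueError(f"all-constant ROI column(s) in run {run}: {bad}")
        if confounds is not None:
            X = _standardize_columns(confounds.iloc[sl].to_numpy(dtype=float))
            X = np.column_stack([np.ones(X.shape[0]), X])
            rank = np.linalg.matrix_rank(X)
            if rank < X.shape[1]:
                logger.warning(
                    "run %d: confound matrix is rank deficient (rank %d of %d); "
                    "collinear directions are dropped by the SVD solve",
                    run,
                    rank,
                    X.shape[1],
                )
            beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
            resid = Y - X @ beta
        else:
            resid = Y - Y.mean(axis=0)
        resid = sp_signal.detrend(resid, axis=0, type="linear")
        rsd = resid.std(axis=0)
        for j in np.flatnonzero(rsd < DEGENERATE_SD):
            degenerate.add(series.roi_names[j])
            logger.warning(
                "run %d: ROI %r residual is degenerate (sd=%.2e); set to zero",
                run,
                series.roi_names[j],
                rsd[j],
            )
        rsd_safe = np.where(rsd < DEGENERATE_SD, 1.0, rsd)
        out[sl] = np.where(rsd < DEGENERATE_SD, 0.0, resid / rsd_safe)
    return RoiTimeSeries(
        values=out,
        roi_names=series.roi_names,
        tr=series.tr,
        run_index=series.run_index.copy(),
        n_nonsteady=dict(series.n_nonsteady),
        degenerate_rois=tuple(sorted(degenerate)),
    )


def filter_correct(events: pd.DataFrame) -> pd.DataFrame:
    """Keep only correct trials with a recorded response time.

    Preserves trial order, logs the number of trials removed per
    condition, and raises if any condition loses all of its trials.
    """
    validate_events(events)
    has_rt = events["response_time"].notna()
    keep = (events["correct"] == 1) & has_rt
    removed = events.loc[~keep]
    for cond, n in removed["trial_type"].value_counts().items():
        logger.info("filter_correct: removed %d trial(s) of condition %r", n, cond)
    out = events.loc[keep].copy()
    for cond in events["trial_type"].unique():
        if (out["trial_type"] == cond).sum() == 0:
            raise ValueError(f"no correct trials remain for condition {cond!r}")
    return out


def epoch_trials(
    residuals: RoiTimeSeries,
    events: pd.DataFrame,
    shift_s: float = 5.0,
    post_duration: float = 10.0,
    subject: str = "",
) -> list[TrialEpoch]:
    """Cut shift-corrected pre/post-decision epochs out of a residual series.

    The series is shifted by ``round(shift_s / tr)`` samples (12 at
    TR = 0.42 s) to compensate for the hemodynamic delay.  For a trial
    with onset ``o`` and response time ``rt`` the pre-decision segment
    covers samples ``[round(o/tr) + k, round((o + rt)/tr) + k)`` and the
    post-decision segment the next ``round(10/tr)`` samples (a fixed 24
    at TR = 0.42 s), where ``k`` is the shift in samples.  Epochs never
    cross run boundaries; trials whose shifted post window would run
    past the end of the run, or whose response time is too short to
    leave at least two pre-decision samples, are dropped with a logged
    reason.

    ``events`` must already be filtered to correct trials.
    """
    validate_events(events)
    if shift_s < 0:
        raise ValueError("shift_s must be non-negative")
    tr = residuals.tr
    k = round_half_up(shift_s / tr)
    post_len = round_half_up(post_duration / tr)
    epochs: list[TrialEpoch] = []
    for trial_id, row in events.iterrows():
        run = int(row["run"])
        sl = residuals.run_slice(run)
        run_len = sl.stop - sl.start
        onset = float(row["onset"])
        rt = float(row["response_time"])
        i_on = round_half_up(onset / tr) + k
        i_resp = round_half_up((onset + rt) / tr) + k
        if i_resp - i_on < 2:
            logger.info(
                "trial %s dropped: rt=%.2fs leaves %d pre samples",
                trial_id,
                rt,
                i_resp - i_on,
            )
            continue
        if i_resp + post_len > run_len:
            logger.info(
                "trial %s dropped: shifted post window exceeds run %d end",
                trial_id,
                run,
            )
            continue
        block = residuals.values[sl]
        epochs.append(
            TrialEpoch(
                trial_id=int(trial_id),
                condition=str(row["trial_type"]),
                pre=block[i_on:i_resp],
                post=block[i_resp : i_resp + post_len],
                rt=rt,
                run=run,
                roi_names=residuals.roi_names,
                tr=tr,
                subject=subject,
            )
        )
    return epochs
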