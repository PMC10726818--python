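"""Profile features: drift slope, peak magnitude, AUC, blockwise metrics.

The condition FIR profile (and each trial's interpolated series) is
summarised by the parameters of the evidence-accumulation reading of
the data:

* *drift rate* — the slope from the minimum coefficient within the first
  5 trial seconds to the maximum coefficient within +/- 3 s of the
  condition's mean decision time;
* *decision threshold* — the peak value near the decision time,
  computed per trial with exclusion rules (a trial is dropped when its
  global maximum is negative or occurs within the first 5 s of the
  reveal) and averaged over the included trials;
* *AUC* — signed trapezoidal area under the coefficient series, over
  the pre-decision window, the post-decision window, or the whole
  reveal period, for step-like and sensory profiles;
* *blockwise metrics* — the same quantities recomputed within scan
  blocks of three runs each, used to resolve habituation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ConditionProfile, InterpolatedTrial
from .profiles import fir_fit
from .synth import run_block

__all__ = [
    "DriftSlope",
    "PeakResult",
    "drift_slope",
    "peak_magnitude",
    "auc",
    "condition_metrics",
    "blockwise_metrics",
]

logger = logging.getLogger(__name__)

#: Early window (s) in which the profile minimum is sought for the slope.
EARLY_WINDOW = 5.0
#: Half-width (s) of the peri-decision window in which peaks are sought.
PEAK_WINDOW = 3.0


@dataclass(frozen=True)
class DriftSlope:
    slope: float
    t_min: float
    v_min: float
    t_peak: float
    v_peak: float
    valid: bool


@dataclass(frozen=True)
class PeakResult:
    value: float
    time: float
    excluded: bool
    reason: str  # "", "negative-maximum" or "early-peak"


def _window_slice(times: np.ndarray, lo: float, hi: float) -> slice:
    """Inclusive bin range with endpoints snapped to the nearest grid bin."""
    lo = max(lo, float(times[0]))
    hi = min(hi, float(times[-1]))
    i0 = int(np.argmin(np.abs(times - lo)))
    i1 = int(np.argmin(np.abs(times - hi)))
    return slice(i0, i1 + 1)


def drift_slope(
    profile: ConditionProfile,
    early_window: float = EARLY_WINDOW,
    peak_window: float = PEAK_WINDOW,
) -> DriftSlope:
    """Slope from the early-window minimum to the peri-decision maximum.

    The minimum is taken over bins with time in [0, 5] s, the maximum
    over bins within +/- ``peak_window`` s of the condition mean
    decision time (clipped to the grid); ties go to the earliest bin.
    A degenerate geometry (peak time at or before the minimum time)
    yields ``valid=False`` rather than a silent zero.
    """
    t = profile.times
    v = profile.coef
    early = _window_slice(t, 0.0, early_window)
    i_min = early.start + int(np.argmin(v[early]))
    peri = _window_slice(t, profile.mean_rt - peak_window, profile.mean_rt + peak_window)
    i_peak = peri.start + int(np.argmax(v[peri]))
    t_min, v_min = float(t[i_min]), float(v[i_min])
    t_peak, v_peak = float(t[i_peak]), float(v[i_peak])
    if t_peak <= t_min:
        return DriftSlope(np.nan, t_min, v_min, t_peak, v_peak, valid=False)
    return DriftSlope(
        (v_peak - v_min) / (t_peak - t_min), t_min, v_min, t_peak, v_peak, valid=True
    )


def peak_magnitude(
    trial: InterpolatedTrial,
    mean_rt: float,
    roi: str | None = None,
    peak_window: float = PEAK_WINDOW,
    early_exclusion: float = EARLY_WINDOW,
) -> PeakResult:
    """Peri-decision peak of one trial, with exclusion rules.

    The peak is the maximum value within +/- ``peak_window`` s of the
    condition mean decision time.  The trial is excluded when its
    *global* maximum is negative (``"negative-maximum"``) or occurs
    within the first ``early_exclusion`` seconds of the reveal
    (``"early-peak"``).
    """
    v = trial.roi_values(roi) if roi is not None else trial.values[:, 0]
    t = trial.times
    sl = _window_slice(t, mean_rt - peak_window, mean_rt + peak_window)
    if sl.stop <= sl.start:
        raise ValueError("empty peri-decision window after clipping")
    i_g = int(np.argmax(v))
    if v[i_g] < 0:
        reason = "negative-maximum"
    elif t[i_g] < early_exclusion:
        reason = "early-peak"
    else:
        reason = ""
    i_w = sl.start + int(np.argmax(v[sl]))
    return PeakResult(
        value=float(v[i_w]),
        time=float(t[i_w]),
        excluded=bool(reason),
        reason=reason,
    )


def auc(
    values: np.ndarray,
    tr: float,
    t0: float,
    t1: float,
    warn_clip: bool = True,
) -> float:
    """Signed trapezoidal area under a coefficient series over [t0, t1].

    Endpoints snap to the nearest grid bin (both inclusive); a ``t1``
    beyond the grid end is clipped with a warning.  Units: value x s.
    """
    values = np.asarray(values, dtype=float)
    times = np.arange(values.shape[0]) * tr
    if t0 >= t1:
        raise ValueError("t0 must precede t1")
    if t1 > times[-1] + tr / 2 and warn_clip:
        logger.warning("auc: t1=%.2fs beyond grid end %.2fs; clipped", t1, times[-1])
    sl = _window_slice(times, t0, t1)
    return float(np.trapezoid(values[sl], dx=tr))


def condition_metrics(
    profile: ConditionProfile,
    trials: Sequence[InterpolatedTrial],
    reveal_duration: float = 25.0,
    peak_window: float = PEAK_WINDOW,
    block: int = 0,
) -> dict:
    """All profile features for one subject x ROI x condition.

    The slope is computed on the condition FIR profile; the peak
    magnitude is computed per trial and averaged over included trials;
    AUCs are computed on the profile over the pre-decision window
    [0, mean_rt], the post-decision window [mean_rt, grid end] and the
    reveal window [0, min(25 s, grid end)].  ``block=0`` denotes the
    whole session.
    """
    ds = drift_slope(profile, peak_window=peak_window)
    cond_trials = [t for t in trials if t.condition == profile.condition]
    peaks = [
        peak_magnitude(t, profile.mean_rt, roi=profile.roi, peak_window=peak_window)
        for t in cond_trials
    ]
    included = [p for p in peaks if not p.excluded]
    n_neg = sum(p.reason == "negative-maximum" for p in peaks)
    n_early = sum(p.reason == "early-peak" for p in peaks)
    for p, t in zip(peaks, cond_trials):
        if p.excluded:
            logger.info(
                "excluded trial %s (subject %s, roi %s): %s",
                t.trial_id,
                profile.subject,
                profile.roi,
                p.reason,
            )
    grid_end = float(profile.times[-1])
    t_dec = min(profile.mean_rt, grid_end - profile.tr)
    return {
        "subject": profile.subject,
        "roi": profile.roi,
        "condition": profile.condition,
        "block": block,
        "slope": ds.slope,
        "slope_valid": ds.valid,
        "slope_min_time": ds.t_min,
        "slope_peak_time": ds.t_peak,
        "profile_peak_value": ds.v_peak,
        "peak": float(np.mean([p.value for p in included])) if included else np.nan,
        "peak_time": float(np.mean([p.time for p in included])) if included else np.nan,
        "auc_pre": auc(profile.coef, profile.tr, 0.0, t_dec),
        "auc_post": auc(profile.coef, profile.tr, t_dec, grid_end),
        "auc_reveal": auc(
            profile.coef, profile.tr, 0.0, min(reveal_duration, grid_end), warn_clip=False
        ),
        "mean_rt": profile.mean_rt,
        "n_trials": profile.n_trials,
        "n_included": len(included),
        "n_excluded_negative": n_neg,
        "n_excluded_early": n_early,
    }


def blockwise_metrics(
    trials_by_cond: dict[str, list[InterpolatedTrial]],
    reveal_duration: float = 25.0,
    peak_window: float = PEAK_WINDOW,
    subject: str = "",
) -> pd.DataFrame:
    """Recompute FIR profiles and metrics within scan blocks of three runs.

    Blocks are runs {1-3}, {4-6}, {7-9}.  A final block with fewer than
    three runs is kept as a partial block with a logged warning; more
    than nine runs is an error (outside the paradigm design).
    """
    rows = []
    for cond, trials in trials_by_cond.items():
        runs = sorted({t.run for t in trials})
        blocks = sorted({run_block(r) for r in runs})
        for b in blocks:
            n_runs_in_block = sum(1 for r in runs if run_block(r) == b)
            if b == blocks[-1] and n_runs_in_block < 3:
                logger.warning(
                    "subject %s: final scan block %d has only %d run(s)",
                    subject,
                    b,
                    n_runs_in_block,
                )
            sel = [t for t in trials if run_block(t.run) == b]
            if not sel:
                continue
            # Trials were interpolated onto the session-level condition
            # grid, so the decision point on the grid is pre_len * tr.
            profs = fir_fit(sel, cond, mean_rt=sel[0].pre_len * sel[0].tr, subject=subject)
            for roi, prof in profs.items():
                rows.append(
                    condition_metrics(
                        prof,
                        sel,
                        reveal_duration=reveal_duration,
                        peak_window=peak_window,
                        block=b,
                    )
                )
    return pd.DataFrame(rows)
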