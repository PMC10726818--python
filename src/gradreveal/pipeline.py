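"""Subject- and experiment-level composition of the pipeline stages.

``analyze_subject`` takes one subject's ROI series, confounds and events
through nuisance regression, correct-trial filtering, hemodynamic
shifting, epoching, common-grid interpolation, FIR estimation and the
profile metrics.  ``run_experiment`` simulates and analyses a whole
group, optionally jittering the generating parameters across subjects,
and returns tidy metric and ground-truth tables — the substrate for the
parameter-recovery and calibration checks.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .containers import RoiTimeSeries
from .extract import epoch_trials, filter_correct, regress_confounds
from .metrics import blockwise_metrics, condition_metrics
from .profiles import fit_condition_profiles
from .synth import GroundTruth, ParadigmConfig, ProfileKind, simulate_subject

__all__ = [
    "analyze_subject",
    "run_experiment",
    "recovery_summary",
    "blockwise_condition_difference",
]


def analyze_subject(
    series: RoiTimeSeries,
    events: pd.DataFrame,
    confounds: pd.DataFrame | None = None,
    subject: str = "sub-01",
    shift_s: float = 5.0,
    peak_window: float = 3.0,
    reveal_duration: float = 25.0,
    grid_lengths: dict[str, int] | None = None,
    compute_blocks: bool = False,
):
    """Run the full per-subject analysis; returns (metrics, profiles).

    ``metrics`` is a tidy DataFrame with one row per ROI x condition
    (block 0 = whole session, plus per-block rows when
    ``compute_blocks``); ``profiles`` maps ``(roi, condition)`` to the
    fitted :class:`~gradreveal.containers.ConditionProfile`.
    """
    resid = regress_confounds(series, confounds)
    ev = filter_correct(events)
    epochs = epoch_trials(resid, ev, shift_s=shift_s, subject=subject)
    if not epochs:
        raise ValueError(f"subject {subject}: no usable epochs")
    surviving = {e.trial_id for e in epochs}
    ev = ev.loc[ev.index.isin(surviving)]
    profiles, trials_by_cond = fit_condition_profiles(
        epochs, ev, tr=series.tr, grid_lengths=grid_lengths, subject=subject
    )
    rows = []
    for (roi, cond), prof in profiles.items():
        rows.append(
            condition_metrics(
                prof,
                trials_by_cond[cond],
                reveal_duration=reveal_duration,
                peak_window=peak_window,
            )
        )
    metrics = pd.DataFrame(rows)
    if compute_blocks:
        bm = blockwise_metrics(
            trials_by_cond,
            reveal_duration=reveal_duration,
            peak_window=peak_window,
            subject=subject,
        )
        metrics = pd.concat([metrics, bm], ignore_index=True)
    return metrics, profiles


def run_experiment(
    n_subjects: int,
    ground_truth: GroundTruth,
    paradigm: ParadigmConfig,
    roi_kinds: Mapping[str, ProfileKind],
    seed: int | np.random.SeedSequence = 0,
    subject_jitter: float = 0.0,
    compute_blocks: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and analyse a group of subjects.

    ``subject_jitter`` introduces between-subject variability in the
    generating parameters as a per-subject *gain* factor drawn
    uniformly from ``[1 - subject_jitter, 1 + subject_jitter]`` and
    applied to both the drift rates and the thresholds of both
    conditions.  Scaling both parameters together models a subject-level
    signal amplitude (BOLD gain) while leaving the behavioural
    predictions (``RT = threshold/drift``) untouched, so the jitter
    spreads the generating parameters across subjects without moving
    response times outside the paradigm's feasible range.  Returns the
    stacked metrics table and a ground-truth table with one row per
    subject x condition.
    """
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    metric_frames = []
    truth_rows = []
    for i, child in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        name = f"sub-{i + 1:02d}"
        if subject_jitter > 0:
            gain = rng.uniform(1 - subject_jitter, 1 + subject_jitter)
            gt_i = ground_truth.scaled(drift_factor=gain, threshold_factor=gain)
        else:
            gt_i = ground_truth
        data = simulate_subject(gt_i, paradigm, roi_kinds, rng=rng, subject=name)
        metrics, _ = analyze_subject(
            data.series,
            data.events,
            confounds=data.confounds,
            subject=name,
            shift_s=paradigm.hrf_shift,
            reveal_duration=paradigm.reveal_duration,
            compute_blocks=compute_blocks,
        )
        metric_frames.append(metrics)
        for cond in gt_i.conditions:
            truth_rows.append(
                {
                    "subject": name,
                    "condition": cond,
                    "drift_rate": gt_i.drift_rate[cond],
                    "threshold": gt_i.threshold[cond],
                }
            )
    return pd.concat(metric_frames, ignore_index=True), pd.DataFrame(truth_rows)


def recovery_summary(
    metrics: pd.DataFrame, truth: pd.DataFrame, roi: str
) -> dict[str, float]:
    """Parameter-recovery summary for one accumulator ROI.

    Merges the recovered slope and mean included peak with the
    generating drift rate and threshold over subject x condition pairs
    and reports Spearman rank correlations plus the group-level
    direction of the condition contrasts (high vs neutral).
    """
    sub = metrics[(metrics["roi"] == roi) & (metrics["block"] == 0)]
    merged = sub.merge(truth, on=["subject", "condition"], validate="one_to_one")
    drift_rho = float(
        sp_stats.spearmanr(merged["drift_rate"], merged["slope"]).statistic
    )
    thresh_rho = float(
        sp_stats.spearmanr(merged["threshold"], merged["peak"]).statistic
    )
    by_cond = merged.groupby("condition")[["slope", "peak"]].mean()
    return {
        "drift_rank_corr": drift_rho,
        "threshold_rank_corr": thresh_rho,
        "slope_high_lt_neutral": float(
            by_cond.loc["high", "slope"] < by_cond.loc["neutral", "slope"]
        ),
        "peak_high_gt_neutral": float(
            by_cond.loc["high", "peak"] > by_cond.loc["neutral", "peak"]
        ),
    }


def blockwise_condition_difference(
    metrics: pd.DataFrame, roi: str, dv: str = "auc_post"
) -> pd.Series:
    """Group-mean condition difference (high - neutral) per scan block."""
    sub = metrics[(metrics["roi"] == roi) & (metrics["block"] > 0)]
    wide = sub.pivot_table(
        index=["subject", "block"], columns="condition", values=dv, observed=True
    )
    diff = (wide["high"] - wide["neutral"]).groupby("block").mean()
    return diff
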