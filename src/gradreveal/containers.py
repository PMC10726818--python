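"""Core data containers shared across the pipeline stages.

The pipeline moves data through a fixed sequence of shapes:

* an *event table* (a :class:`pandas.DataFrame` in the BIDS events dialect)
  holding per-trial onsets, response times, condition labels, correctness
  and run indices;
* a :class:`RoiTimeSeries` holding the sampled BOLD signal (or its
  residuals after nuisance regression) for one or more regions of
  interest;
* a :class:`TrialEpoch` holding the residual segments of a single trial,
  split at the behavioural response into a variable-length pre-decision
  part and a fixed 10-s post-decision part;
* an :class:`InterpolatedTrial` holding a trial resampled onto its
  condition's common grid and zero-locked;
* a :class:`ConditionProfile` holding the FIR coefficient series that
  summarises all of a subject's trials for one ROI and condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "RoiTimeSeries",
    "TrialEpoch",
    "InterpolatedTrial",
    "ConditionProfile",
    "validate_events",
    "round_half_up",
]

#: Columns an event table must carry (BIDS events dialect plus run index).
EVENT_COLUMNS = ("onset", "duration", "trial_type", "response_time", "correct", "run")


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up.

    Sample-index arithmetic throughout the pipeline uses this rule so
    that e.g. a 5-s hemodynamic shift at TR = 0.42 s is always 12
    samples and a 10-s post-decision window is always 24 samples,
    independent of the platform's banker's rounding.
    """
    return int(np.floor(float(x) + 0.5))


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check that an event table has the expected columns and dtypes."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")
    if events["onset"].lt(0).any():
        raise ValueError("event onsets must be non-negative")
    if events["run"].lt(1).any():
        raise ValueError("run indices are 1-based")
    return events


@dataclass
class RoiTimeSeries:
    """Sampled BOLD (or residual) values for a set of ROIs.

    Parameters
    ----------
    values
        Array of shape ``(n_samples, n_rois)``.
    roi_names
        One name per column of ``values``.
    tr
        Sampling interval in seconds.
    run_index
        1-based run label per sample, shape ``(n_samples,)``.  Runs must
        be contiguous and equally long within a session.
    n_nonsteady
        Number of non-steady-state volumes at the start of each run.
    degenerate_rois
        ROIs whose residuals collapsed to (numerically) zero during
        nuisance regression; populated by
        :func:`gradreveal.extract.regress_confounds`.
    """

    values: np.ndarray
    roi_names: tuple[str, ...]
    tr: float
    run_index: np.ndarray
    n_nonsteady: dict[int, int] = field(default_factory=dict)
    degenerate_rois: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        self.run_index = np.asarray(self.run_index, dtype=int)
        self.roi_names = tuple(self.roi_names)
        if self.values.shape[1] != len(self.roi_names):
            raise ValueError("number of ROI names must match value columns")
        if self.values.shape[0] != self.run_index.shape[0]:
            raise ValueError("run_index length must match sample count")
        if np.isnan(self.values).any():
            raise ValueError("ROI time series contains NaNs")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        lengths = {int(n) for n in np.bincount(self.run_index)[1:] if n > 0}
        if len(lengths) > 1:
            raise ValueError(f"runs have unequal lengths: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def runs(self) -> list[int]:
        return sorted(int(r) for r in np.unique(self.run_index))

    def run_slice(self, run: int) -> slice:
        idx = np.flatnonzero(self.run_index == run)
        if idx.size == 0:
            raise KeyError(f"run {run} not present")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def roi_column(self, roi: str) -> int:
        try:
            return self.roi_names.index(roi)
        except ValueError:
            raise KeyError(f"unknown ROI {roi!r}") from None


@dataclass
class TrialEpoch:
    """Residual segments of one trial, split at the (shifted) response.

    ``pre`` covers the shifted interval from trial onset to the decision
    response and varies in length with the response time; ``post``
    covers exactly the 10 s after the decision and therefore has the
    same number of samples for every trial.
    """

    trial_id: int
    condition: str
    pre: np.ndarray  # (n_pre, n_rois)
    post: np.ndarray  # (n_post, n_rois)
    rt: float
    run: int
    roi_names: tuple[str, ...]
    tr: float
    subject: str = ""

    def __post_init__(self) -> None:
        self.pre = np.atleast_2d(np.asarray(self.pre, dtype=float))
        self.post = np.atleast_2d(np.asarray(self.post, dtype=float))
        if self.pre.shape[0] < 2:
            raise ValueError("pre-decision segment needs at least 2 samples")


@dataclass
class InterpolatedTrial:
    """One trial conformed to its condition's common grid and zero-locked.

    ``values`` has ``pre_len + post_len`` rows; the first ``pre_len``
    rows are the linearly resampled pre-decision segment, the remaining
    rows are the post-decision segment copied without resampling.  The
    whole series has been shifted so the first row is exactly zero;
    ``zero_ref`` records the per-ROI offset that was subtracted.
    """

    trial_id: int
    condition: str
    values: np.ndarray  # (pre_len + post_len, n_rois)
    pre_len: int
    zero_ref: np.ndarray  # (n_rois,)
    roi_names: tuple[str, ...]
    tr: float
    run: int
    rt: float
    subject: str = ""

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.tr

    def roi_values(self, roi: str) -> np.ndarray:
        return self.values[:, self.roi_names.index(roi)]


@dataclass
class ConditionProfile:
    """FIR coefficient series for one subject x ROI x condition.

    ``coef[k]`` estimates the mean residual amplitude ``k * tr`` seconds
    after (shift-corrected) trial onset on the condition's common grid.
    ``mean_rt`` is the mean correct response time that defined the grid
    and anchors the decision point for the downstream metrics.
    """

    subject: str
    roi: str
    condition: str
    coef: np.ndarray
    n_trials: int
    mean_rt: float
    tr: float
    pre_len: int

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float).ravel()
        if self.n_trials < 1:
            raise ValueError("a condition profile needs at least one trial")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.coef.shape[0]) * self.tr


def stack_roi_names(epochs: Sequence[TrialEpoch]) -> tuple[str, ...]:
    names = {e.roi_names for e in epochs}
    if len(names) != 1:
        raise ValueError("epochs mix different ROI sets")
    return names.pop()
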