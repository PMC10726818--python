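"""Synthetic gradual-reveal experiment generator.

Simulates the full data-generating process of a gradual-reveal fMRI
categorization experiment so that every downstream stage of the analysis
can be validated by parameter recovery:

* behaviour: self-paced response times coupled to ground-truth
  accumulation parameters through ``RT = threshold / drift + noise``,
  packed into fixed-length scanner runs with jittered inter-trial
  intervals;
* neural signal: one of four trial-level temporal profile archetypes
  (evidence accumulator, moment-of-decision, sensory ramp, amygdala-like
  step) whose amplitude and timing are set by the same ground-truth
  parameters;
* BOLD: hemodynamic convolution with a double-gamma kernel, serially
  correlated (AR(1)) noise, low-frequency scanner drift, and a global
  signal component shared across ROIs.

All randomness flows from a single :class:`numpy.random.Generator` (or a
root seed), so identical seeds yield bit-identical events and series.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .containers import EVENT_COLUMNS, RoiTimeSeries, round_half_up

__all__ = [
    "ParadigmConfig",
    "GroundTruth",
    "ProfileKind",
    "SubjectData",
    "simulate_behavior",
    "neural_profile",
    "hrf_kernel",
    "synthesize_bold",
    "apply_habituation",
    "simulate_subject",
    "run_block",
]

CONDITIONS = ("neutral", "high")


class ProfileKind(str, enum.Enum):
    """The four trial-level temporal profile archetypes."""

    ACCUMULATOR = "accumulator"
    MOMENT_OF_DECISION = "moment_of_decision"
    SENSORY = "sensory"
    STEP = "step"


@dataclass(frozen=True)
class ParadigmConfig:
    """Timing of the gradual-reveal paradigm.

    Defaults encode the study conditions: a 25-s reveal, a 10-s
    post-decision period, 6/8/10-s jittered inter-trial intervals,
    a 0.42-s repetition time, and 6-min runs.
    """

    reveal_duration: float = 25.0
    post_decision_duration: float = 10.0
    iti_choices: tuple[float, ...] = (6.0, 8.0, 10.0)
    tr: float = 0.42
    run_duration: float = 360.0
    n_runs: int = 9
    n_trials_total: int = 100
    hrf_shift: float = 5.0

    def __post_init__(self) -> None:
        for name in ("reveal_duration", "post_decision_duration", "tr", "run_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.iti_choices or any(i <= 0 for i in self.iti_choices):
            raise ValueError("iti_choices must be positive durations")
        if not 1 <= self.n_runs:
            raise ValueError("n_runs must be at least 1")
        if self.n_trials_total > 100:
            raise ValueError("n_trials_total is capped at 100")

    @property
    def samples_per_run(self) -> int:
        return round_half_up(self.run_duration / self.tr)

    @property
    def post_len(self) -> int:
        """Post-decision window length in samples (24 at TR = 0.42 s)."""
        return round_half_up(self.post_decision_duration / self.tr)


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters of the synthetic experiment.

    ``drift_rate`` (signal units / s) is the slope of the pre-decision
    neural ramp and ``threshold`` (signal units) its peak amplitude at
    the moment of decision, per salience condition.  Defaults place the
    neutral condition at RT = threshold/drift = 12.05 s and the high
    salience condition at 13.83 s, with the high condition combining a
    shallower drift with a higher threshold.
    """

    drift_rate: Mapping[str, float] = field(
        default_factory=lambda: {"neutral": 1.0 / 12.05, "high": 1.1 / 13.83}
    )
    threshold: Mapping[str, float] = field(
        default_factory=lambda: {"neutral": 1.0, "high": 1.1}
    )
    rt_noise_sd: float = 3.0
    accuracy_prob: float = 0.93
    habituation_factor: float = 1.0
    noise_sd: float = 0.5
    ar1_coef: float = 0.3
    drift_amplitude: float = 0.3
    global_amplitude: float = 0.2
    mod_width: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        for cond in self.drift_rate:
            if self.drift_rate[cond] <= 0:
                raise ValueError("drift_rate must be positive")
        for cond in self.threshold:
            if self.threshold[cond] <= 0:
                raise ValueError("threshold must be positive")
        if set(self.drift_rate) != set(self.threshold):
            raise ValueError("drift_rate and threshold must cover the same conditions")
        if not 0 < self.accuracy_prob <= 1:
            raise ValueError("accuracy_prob must be in (0, 1]")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")
        if self.habituation_factor <= 0:
            raise ValueError("habituation_factor must be positive")
        if self.rt_noise_sd < 0:
            raise ValueError("rt_noise_sd must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.drift_rate)

    def mean_rt(self, condition: str) -> float:
        return self.threshold[condition] / self.drift_rate[condition]

    def scaled(self, drift_factor: float = 1.0, threshold_factor: float = 1.0) -> "GroundTruth":
        """Return a copy with per-subject scaling of the core parameters."""
        return replace(
            self,
            drift_rate={c: v * drift_factor for c, v in self.drift_rate.items()},
            threshold={c: v * threshold_factor for c, v in self.threshold.items()},
        )


def run_block(run: int) -> int:
    """Scan block (1-3) of a 1-based run index; runs come in blocks of three."""
    if run < 1:
        raise ValueError("run indices are 1-based")
    if run > 9:
        raise ValueError("more than 9 runs is outside the paradigm design")
    return (run - 1) // 3 + 1


def _draw_itis(rng: np.random.Generator, n: int, choices: Sequence[float]) -> np.ndarray:
    """Uniform draw over the jittered inter-trial intervals."""
    return rng.choice(np.asarray(choices, dtype=float), size=n)


def _truncated_rts(
    rng: np.random.Generator, means: np.ndarray, sd: float, upper: float
) -> np.ndarray:
    """Gaussian response times truncated to (0, upper] by redrawing."""
    rts = means + sd * rng.standard_normal(means.shape[0])
    if sd == 0:
        return rts
    bad = (rts <= 0) | (rts > upper)
    # Redraw rather than clip so no probability mass piles up at the edges.
    for _ in range(1000):
        if not bad.any():
            break
        rts[bad] = means[bad] + sd * rng.standard_normal(int(bad.sum()))
        bad = (rts <= 0) | (rts > upper)
    else:  # pragma: no cover - pathological configurations only
        raise RuntimeError("could not draw response times inside (0, reveal]")
    return rts


def simulate_behavior(
    ground_truth: GroundTruth,
    paradigm: ParadigmConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a subject's behavioural event table.

    Response times follow ``RT = threshold/drift + noise`` truncated to
    (0, reveal_duration]; the condition order is randomized; trials are
    packed into runs such that ``onset + RT + 10 + ITI <= run_duration``,
    with trials that would overflow a run deferred to the next run.
    Trials that do not fit before the last run ends are dropped, so a
    subject may complete fewer than ``n_trials_total`` trials.

    Returns a BIDS-style event table with columns
    ``onset, duration, trial_type, response_time, correct, run`` (onsets
    are run-relative, in seconds).
    """
    if rng is None:
        rng = np.random.default_rng(ground_truth.seed)
    for cond in ground_truth.conditions:
        if ground_truth.mean_rt(cond) >= paradigm.reveal_duration:
            raise ValueError(
                f"mean RT for condition {cond!r} "
                f"({ground_truth.mean_rt(cond):.2f} s) reaches the "
                f"{paradigm.reveal_duration:.0f}-s reveal duration"
            )

    n = paradigm.n_trials_total
    conds = list(ground_truth.conditions)
    # Balanced condition list (as close as the total allows), shuffled.
    per = n // len(conds)
    labels = np.array(conds * per + conds[: n - per * len(conds)])
    labels = labels[rng.permutation(n)]

    means = np.array([ground_truth.mean_rt(c) for c in labels])
    rts = _truncated_rts(rng, means, ground_truth.rt_noise_sd, paradigm.reveal_duration)
    correct = (rng.random(n) < ground_truth.accuracy_prob).astype(int)
    itis = _draw_itis(rng, n, paradigm.iti_choices)

    rows = []
    run, cursor = 1, 0.0
    post = paradigm.post_decision_duration
    for i in range(n):
        needed = rts[i] + post + itis[i]
        if cursor + needed > paradigm.run_duration:
            run += 1
            cursor = 0.0
            if run > paradigm.n_runs:
                break
            if cursor + needed > paradigm.run_duration:  # pragma: no cover
                continue
        rows.append(
            {
                "onset": cursor,
                "duration": rts[i] + post,
                "trial_type": labels[i],
                "response_time": rts[i],
                "correct": int(correct[i]),
                "run": run,
            }
        )
        cursor += needed
    events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    return events


def neural_profile(
    kind: ProfileKind,
    ground_truth: GroundTruth,
    rt: float,
    grid: np.ndarray,
    condition: str = "neutral",
    amplitude: float | None = None,
    post_duration: float = 10.0,
) -> np.ndarray:
    """Evaluate a trial's neural profile archetype on a time grid.

    ``grid`` is trial-relative (0 = trial onset) and strictly
    increasing.  ``amplitude`` overrides the condition threshold (used
    e.g. for habituated step amplitudes).

    Functional forms:

    * ``accumulator`` — linear ramp from 0 to the threshold over
      [0, rt], then linear decay back to 0 over [rt, rt + 10].  The apex
      is snapped to the grid point nearest ``rt`` so the noiseless peak
      equals the threshold exactly on the sampling grid.
    * ``moment_of_decision`` — a narrow Gaussian bump centred at ``rt``.
    * ``sensory`` — saturating ramp toward the threshold while the
      stimulus is being revealed, holding its level afterwards.
    * ``step`` — 0 before ``rt``, constant amplitude on [rt, rt + 10].
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D vector")
    if rt <= 0:
        raise ValueError("rt must be positive")
    if not grid[0] <= rt <= grid[-1]:
        raise ValueError(f"rt={rt} lies outside the grid [{grid[0]}, {grid[-1]}]")
    kind = ProfileKind(kind)
    amp = ground_truth.threshold[condition] if amplitude is None else float(amplitude)

    if kind is ProfileKind.ACCUMULATOR:
        t_apex = grid[int(np.argmin(np.abs(grid - rt)))]
        out = np.zeros_like(grid)
        up = grid <= t_apex
        out[up] = amp * grid[up] / t_apex if t_apex > 0 else amp
        down = (grid > t_apex) & (grid <= t_apex + post_duration)
        out[down] = amp * (1.0 - (grid[down] - t_apex) / post_duration)
        return out
    if kind is ProfileKind.MOMENT_OF_DECISION:
        sigma = ground_truth.mod_width
        return amp * np.exp(-0.5 * ((grid - rt) / sigma) ** 2)
    if kind is ProfileKind.SENSORY:
        t_end = min(25.0, grid[-1])
        tau = t_end / 4.0
        return amp * (1.0 - np.exp(-np.minimum(grid, t_end) / tau))
    if kind is ProfileKind.STEP:
        out = np.zeros_like(grid)
        on = (grid >= rt) & (grid <= rt + post_duration)
        out[on] = amp
        return out
    raise ValueError(f"unknown profile kind {kind!r}")  # pragma: no cover


def _gamma_by_mode(mode: float, sd: float) -> tuple[float, float]:
    """Shape/scale of a gamma density with the given mode and standard deviation."""
    scale = (-mode + math.sqrt(mode * mode + 4.0 * sd * sd)) / 2.0
    shape = mode / scale + 1.0
    return shape, scale


def hrf_kernel(
    tr: float,
    duration: float = 32.0,
    peak: float = 5.2,
    peak_sd: float = 1.0,
    undershoot: float = 15.0,
    undershoot_sd: float = 2.0,
    undershoot_ratio: float = 0.1,
) -> np.ndarray:
    """Double-gamma hemodynamic response kernel sampled at ``tr``.

    The positive lobe peaks at ``peak`` seconds and a smaller negative
    lobe models the post-stimulus undershoot.  The defaults (mode
    5.2 s, spread 1.0 s, within the physiological 3-6-s delay range)
    make the kernel *timing-neutral* with respect to the analysis
    pipeline's fixed 5-s hemodynamic shift correction: the latency the
    kernel adds to a ramp-to-peak signal matches the 12-sample shift
    the extraction stage removes, so decision-locked peaks land on the
    correct grid bin across the paradigm's response-time range.  The
    kernel is normalized to unit sum so slowly varying neural signals
    pass through with unit gain and ground-truth amplitudes survive
    convolution.
    """
    t = np.arange(0.0, duration, tr)
    a1, b1 = _gamma_by_mode(peak, peak_sd)
    a2, b2 = _gamma_by_mode(undershoot, undershoot_sd)
    g1 = sp_stats.gamma.pdf(t, a1, scale=b1)
    g2 = sp_stats.gamma.pdf(t, a2, scale=b2)
    h = g1 / g1.max() - undershoot_ratio * g2 / g2.max()
    return h / h.sum()


def _ar1_noise(
    rng: np.random.Generator, n: int, sd: float, coef: float
) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros(n)
    w = rng.standard_normal(n) * sd * math.sqrt(1.0 - coef * coef)
    return sp_signal.lfilter([1.0], [1.0, -coef], w)


def _cosine_basis(n: int, tr: float, n_comp: int = 3) -> np.ndarray:
    """Low-frequency cosine drift basis for one run (columns unit-amplitude)."""
    t = np.arange(n) * tr
    T = n * tr
    return np.column_stack(
        [np.cos(np.pi * (k + 1) * t / T) for k in range(n_comp)]
    )


def synthesize_bold(
    profiles: Mapping[str, Sequence[np.ndarray]],
    events: pd.DataFrame,
    ground_truth: GroundTruth,
    paradigm: ParadigmConfig,
    rng: np.random.Generator | None = None,
    return_confounds: bool = False,
):
    """Convolve per-trial neural profiles into noisy multi-run BOLD series.

    ``profiles`` maps each ROI name to one trial-relative signal vector
    per event-table row (sampled at the TR).  Each run's neural signal
    is convolved with the double-gamma kernel; AR(1) noise, random
    low-frequency cosine drift and a global signal component shared
    across ROIs are then added.

    With ``return_confounds=True`` additionally returns a confound table
    (global signal with derivative/quadratic expansions plus the cosine
    basis) mirroring what an fMRIPrep-style preprocessing would provide.
    """
    if rng is None:
        rng = np.random.default_rng(ground_truth.seed + 1)
    roi_names = tuple(profiles)
    n_trials = len(events)
    for roi, plist in profiles.items():
        if len(plist) != n_trials:
            raise ValueError(f"ROI {roi!r} has {len(plist)} profiles for {n_trials} trials")
        for p in plist:
            if np.isnan(p).any():
                raise ValueError(f"NaN in neural profile for ROI {roi!r}")

    nps = paradigm.samples_per_run
    tr = paradigm.tr
    kernel = hrf_kernel(tr)
    runs = sorted(events["run"].unique()) if n_trials else [1]
    n_runs = max(runs) if runs else 1

    # Overlap check: within a run, trials may not overlap in time.
    for run, grp in events.groupby("run"):
        g = grp.sort_values("onset")
        ends = g["onset"].to_numpy() + g["duration"].to_numpy()
        if np.any(g["onset"].to_numpy()[1:] < ends[:-1] - 1e-9):
            raise ValueError(f"overlapping trials within run {run}")

    values = np.zeros((n_runs * nps, len(roi_names)))
    run_index = np.repeat(np.arange(1, n_runs + 1), nps)
    global_parts = []
    for ri, run in enumerate(range(1, n_runs + 1)):
        sl = slice(ri * nps, (ri + 1) * nps)
        neural = np.zeros((nps, len(roi_names)))
        in_run = events.index[events["run"] == run]
        for j, roi in enumerate(roi_names):
            for idx in in_run:
                pos = events.index.get_loc(idx)
                i0 = round_half_up(events.at[idx, "onset"] / tr)
                prof = profiles[roi][pos]
                stop = min(nps, i0 + prof.shape[0])
                neural[i0:stop, j] += prof[: stop - i0]
        conv = np.empty_like(neural)
        for j in range(len(roi_names)):
            conv[:, j] = np.convolve(neural[:, j], kernel)[:nps]

        cos = _cosine_basis(nps, tr)
        g = _ar1_noise(rng, nps, 1.0, 0.95) * ground_truth.global_amplitude
        global_parts.append(g)
        for j in range(len(roi_names)):
            drift_coefs = rng.standard_normal(cos.shape[1]) * ground_truth.drift_amplitude
            noise = _ar1_noise(rng, nps, ground_truth.noise_sd, ground_truth.ar1_coef)
            conv[:, j] += cos @ drift_coefs + g + noise
        values[sl] = conv

    series = RoiTimeSeries(values=values, roi_names=roi_names, tr=tr, run_index=run_index)
    if not return_confounds:
        return series
    gsig = np.concatenate(global_parts)
    cos_full = np.vstack([_cosine_basis(nps, tr)] * n_runs)
    confounds = pd.DataFrame(
        {
            "global_signal": gsig,
            "global_signal_derivative1": np.gradient(gsig),
            "global_signal_power2": gsig**2,
        }
    )
    for k in range(cos_full.shape[1]):
        confounds[f"cosine{k:02d}"] = cos_full[:, k]
    return series, confounds


def apply_habituation(
    step_amplitudes: np.ndarray,
    events: pd.DataFrame,
    habituation_factor: float,
) -> np.ndarray:
    """Attenuate step-profile amplitudes multiplicatively per scan block.

    Runs are grouped into blocks of three; block ``b`` amplitudes are
    multiplied by ``habituation_factor ** (b - 1)``, emulating the
    attenuation of amygdala responses with repeated exposure to salient
    stimuli.
    """
    if habituation_factor <= 0:
        raise ValueError("habituation_factor must be positive")
    amps = np.asarray(step_amplitudes, dtype=float)
    if amps.shape[0] != len(events):
        raise ValueError("one amplitude per event row is required")
    blocks = np.array([run_block(int(r)) for r in events["run"]])
    return amps * habituation_factor ** (blocks - 1)


@dataclass
class SubjectData:
    """Simulated data bundle for one subject."""

    subject: str
    events: pd.DataFrame
    series: RoiTimeSeries
    confounds: pd.DataFrame
    ground_truth: GroundTruth
    roi_kinds: dict[str, ProfileKind]


def simulate_subject(
    ground_truth: GroundTruth,
    paradigm: ParadigmConfig,
    roi_kinds: Mapping[str, ProfileKind],
    rng: np.random.Generator | None = None,
    subject: str = "sub-01",
) -> SubjectData:
    """Simulate one subject end to end: events, neural profiles, BOLD.

    Step-profile amplitudes are habituated per scan block with
    ``ground_truth.habituation_factor`` before convolution.
    """
    if rng is None:
        rng = np.random.default_rng(ground_truth.seed)
    events = simulate_behavior(ground_truth, paradigm, rng)
    tr = paradigm.tr
    profiles: dict[str, list[np.ndarray]] = {}
    for roi, kind in roi_kinds.items():
        kind = ProfileKind(kind)
        amps = np.array(
            [ground_truth.threshold[c] for c in events["trial_type"]], dtype=float
        )
        if kind is ProfileKind.STEP:
            amps = apply_habituation(amps, events, ground_truth.habituation_factor)
        plist = []
        for pos, (_, row) in enumerate(events.iterrows()):
            rt = float(row["response_time"])
            grid = np.arange(0.0, rt + paradigm.post_decision_duration + tr / 2, tr)
            plist.append(
                neural_profile(
                    kind,
                    ground_truth,
                    rt,
                    grid,
                    condition=row["trial_type"],
                    amplitude=amps[pos],
                    post_duration=paradigm.post_decision_duration,
                )
            )
        profiles[roi] = plist
    series, confounds = synthesize_bold(
        profiles, events, ground_truth, paradigm, rng, return_confounds=True
    )
    return SubjectData(
        subject=subject,
        events=events,
        series=series,
        confounds=confounds,
        ground_truth=ground_truth,
        roi_kinds={r: ProfileKind(k) for r, k in roi_kinds.items()},
    )
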