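"""Inferential layer: paired t-tests, repeated-measures ANOVA, Bonferroni.

Pure functions over tidy metric tables.  The repeated-measures ANOVA
uses the classical within-subject convention in which each effect is
tested against its own effect x subject interaction mean square
(delegated to :class:`statsmodels.stats.anova.AnovaRM`); a 2-level
single-factor design therefore reproduces the paired t-test through
``F = t**2``.  A small simulation harness (:func:`null_calibration`)
checks that the full pipeline plus ANOVA rejects at the nominal rate
when the generating parameters carry no condition effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "PairedTestResult",
    "AnovaEffect",
    "paired_t",
    "rm_anova",
    "bonferroni",
    "null_calibration",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    degenerate: bool = False
    p_adjusted: float | None = None


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df_num: int
    df_den: int
    p: float


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Classical two-sided paired t-test on subject-aligned values.

    Zero-variance differences are reported with a ``degenerate`` flag
    instead of an infinite statistic; the all-equal case (mean
    difference also zero) conventionally yields ``t = 0, p = 1``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    d = x - y
    n = d.size
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if md == 0.0:
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0, degenerate=True)
        return PairedTestResult(t=np.nan, df=n - 1, p=np.nan, mean_diff=md, degenerate=True)
    t = md / (sd / np.sqrt(n))
    p = 2.0 * sp_stats.t.sf(abs(t), n - 1)
    return PairedTestResult(t=float(t), df=n - 1, p=float(p), mean_diff=md)


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject",
) -> list[AnovaEffect]:
    """Repeated-measures ANOVA with subject as random factor.

    Supports one to three within-subject factors.  Replicate rows in a
    cell are aggregated by the mean; subjects with missing cells are
    dropped listwise with a warning.  Each effect is tested against its
    own effect x subject interaction mean square (classical
    repeated-measures error terms).
    """
    from statsmodels.stats.anova import AnovaRM

    within = list(within)
    if not 1 <= len(within) <= 3:
        raise ValueError("rm_anova supports 1-3 within factors")
    for f in within:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
    cells_per_subject = int(np.prod([table[f].nunique() for f in within]))
    agg = table.groupby([subject, *within], as_index=False, observed=True)[dv].mean()
    counts = agg.groupby(subject, observed=True).size()
    complete = counts[counts == cells_per_subject].index
    dropped = sorted(set(counts.index) - set(complete))
    if dropped:
        logger.warning("rm_anova: dropping subjects with missing cells: %s", dropped)
    agg = agg[agg[subject].isin(complete)]
    if agg[subject].nunique() < 3:
        raise ValueError("rm_anova needs at least 3 complete subjects")
    res = AnovaRM(agg, depvar=dv, subject=subject, within=within).fit()
    out = []
    for name, row in res.anova_table.iterrows():
        out.append(
            AnovaEffect(
                name=str(name),
                F=float(row["F Value"]),
                df_num=int(round(row["Num DF"])),
                df_den=int(round(row["Den DF"])),
                p=float(row["Pr > F"]),
            )
        )
    return out


def bonferroni(p_values: Sequence[float], family_size: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: each p multiplied by the family size, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if family_size is None else int(family_size)
    if m < 1:
        raise ValueError("family_size must be at least 1")
    return np.minimum(1.0, m * p)


def null_calibration(
    sim_config: dict,
    n_reps: int,
    alpha: float,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the pipeline's condition test.

    Simulates ``n_reps`` experiments whose generating parameters are
    identical across salience conditions, runs the full
    simulate-extract-profile-metrics pipeline, tests the condition main
    effect on the drift slope with :func:`rm_anova`, and returns the
    fraction of repetitions with ``p < alpha``.

    ``sim_config`` keys (all optional): ``n_subjects``, ``n_trials``,
    ``ground_truth`` (a :class:`~gradreveal.synth.GroundTruth`),
    ``paradigm`` (a :class:`~gradreveal.synth.ParadigmConfig`), ``dv``.
    """
    from .pipeline import run_experiment
    from .synth import GroundTruth, ParadigmConfig, ProfileKind

    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    n_subjects = sim_config.get("n_subjects", 10)
    dv = sim_config.get("dv", "slope")
    gt = sim_config.get("ground_truth")
    if gt is None:
        # Identical parameters in both conditions: the exact null.
        gt = GroundTruth(
            drift_rate={"neutral": 0.085, "high": 0.085},
            threshold={"neutral": 1.0, "high": 1.0},
            rt_noise_sd=2.0,
        )
    paradigm = sim_config.get(
        "paradigm",
        ParadigmConfig(n_runs=6, n_trials_total=sim_config.get("n_trials", 40)),
    )
    rois = sim_config.get("rois", {"acc": ProfileKind.ACCUMULATOR})
    root = np.random.SeedSequence(seed)
    rejections = 0
    valid = 0
    for child in root.spawn(n_reps):
        metrics, _ = run_experiment(
            n_subjects=n_subjects,
            ground_truth=gt,
            paradigm=paradigm,
            roi_kinds=rois,
            seed=child,
        )
        sub = metrics[metrics["block"] == 0]
        try:
            effects = rm_anova(sub, dv=dv, within=["condition"])
        except ValueError:  # pragma: no cover - degenerate experiment
            continue
        valid += 1
        p = next(e.p for e in effects if e.name == "condition")
        if p < alpha:
            rejections += 1
    if valid == 0:
        raise RuntimeError("no valid repetitions")
    return rejections / valid
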