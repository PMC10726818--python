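"""End-to-end runs: simulate, analyse, test, plot, with a manifest.

``run_all`` turns a :class:`~gradreveal.config.RunConfig` into a
deterministic directory layout::

    run/
      config.yaml          resolved configuration + seed + hash
      ground_truth.yaml    generating parameters
      events/sub-XX.tsv    simulated behaviour (BIDS events dialect)
      series/sub-XX.tsv    simulated ROI BOLD series
      confounds/sub-XX.tsv simulated confound tables
      metrics.tsv          tidy per subject x ROI x condition (x block) metrics
      stats/               ANOVA/t-test reports (TSV + markdown summary)
      figures/             per-ROI condition profiles, blockwise step panels

``make_fixtures`` writes a small frozen bundle (2 subjects, 2 runs, 12
trials) with hand-checkable content for unit tests and demos.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, config_hash, resolved_yaml
from .containers import ConditionProfile
from .extract import epoch_trials, filter_correct, regress_confounds
from .io import write_confounds, write_events, write_ground_truth, write_series
from .metrics import blockwise_metrics, condition_metrics
from .pipeline import analyze_subject
from .profiles import fit_condition_profiles
from .stats import AnovaEffect, bonferroni, paired_t, rm_anova
from .synth import ProfileKind, run_block, simulate_subject

__all__ = ["run_all", "make_fixtures"]

logger = logging.getLogger(__name__)


def _mean_profile(profiles: list[ConditionProfile]) -> ConditionProfile | None:
    """Average condition profiles across subjects on a common grid.

    Subject grids differ in pre-decision length; each profile's pre part
    is linearly resampled onto the median pre-length before averaging,
    the fixed-length post part is averaged directly.
    """
    if not profiles:
        return None
    post_len = profiles[0].coef.shape[0] - profiles[0].pre_len
    target_pre = int(np.median([p.pre_len for p in profiles]))
    resampled = []
    for p in profiles:
        pre = p.coef[: p.pre_len]
        post = p.coef[p.pre_len :]
        src = np.linspace(0, 1, pre.shape[0])
        dst = np.linspace(0, 1, target_pre)
        resampled.append(np.concatenate([np.interp(dst, src, pre), post[:post_len]]))
    coef = np.mean(resampled, axis=0)
    return ConditionProfile(
        subject="group",
        roi=profiles[0].roi,
        condition=profiles[0].condition,
        coef=coef,
        n_trials=sum(p.n_trials for p in profiles),
        mean_rt=float(np.mean([p.mean_rt for p in profiles])),
        tr=profiles[0].tr,
        pre_len=target_pre,
    )


def _effects_frame(effects: list[AnovaEffect], label: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "analysis": label,
                "effect": e.name,
                "F": e.F,
                "df_num": e.df_num,
                "df_den": e.df_den,
                "p": e.p,
            }
            for e in effects
        ]
    )


def _group_stats(metrics: pd.DataFrame, config: RunConfig) -> tuple[pd.DataFrame, str]:
    """The study's inferential layer on the tidy metrics table."""
    frames: list[pd.DataFrame] = []
    lines: list[str] = ["# Group statistics", ""]
    session = metrics[metrics["block"] == 0]
    kinds = {roi: k for roi, k in config.rois.items()}
    acc_rois = [r for r, k in kinds.items() if k is ProfileKind.ACCUMULATOR]
    step_rois = [r for r, k in kinds.items() if k is ProfileKind.STEP]
    sensory_rois = [r for r, k in kinds.items() if k is ProfileKind.SENSORY]

    for dv, label in (("slope", "drift rate"), ("peak", "decision threshold")):
        sub = session[session["roi"].isin(acc_rois)].dropna(subset=[dv])
        if sub.empty or sub["condition"].nunique() < 2:
            continue
        within = ["roi", "condition"] if len(acc_rois) > 1 else ["condition"]
        try:
            effects = rm_anova(sub, dv=dv, within=within)
        except ValueError as err:
            lines.append(f"- {label}: ANOVA skipped ({err})")
            continue
        frames.append(_effects_frame(effects, f"accumulator {label} ({dv})"))
        cond_eff = next((e for e in effects if e.name == "condition"), None)
        if cond_eff:
            lines.append(
                f"- accumulator {label}: condition F({cond_eff.df_num}, "
                f"{cond_eff.df_den}) = {cond_eff.F:.2f}, p = {cond_eff.p:.4g}"
            )
        # Pairwise high-vs-neutral per ROI, Bonferroni over the ROI family.
        raws = []
        for roi in acc_rois:
            w = sub[sub["roi"] == roi].pivot(
                index="subject", columns="condition", values=dv
            )
            if {"high", "neutral"} <= set(w.columns):
                res = paired_t(w["high"].to_numpy(), w["neutral"].to_numpy())
                raws.append((roi, res))
        if raws:
            adj = bonferroni([r.p for _, r in raws], len(raws))
            for (roi, res), pa in zip(raws, adj):
                lines.append(
                    f"  - {roi} {label}: t({res.df}) = {res.t:.2f}, "
                    f"p_bonf = {pa:.4g} (mean diff {res.mean_diff:+.3f})"
                )

    for roi in step_rois:
        sub = session[session["roi"] == roi]
        long = sub.melt(
            id_vars=["subject", "condition"],
            value_vars=["auc_pre", "auc_post"],
            var_name="period",
            value_name="auc",
        )
        try:
            effects = rm_anova(long, dv="auc", within=["condition", "period"])
            frames.append(_effects_frame(effects, f"{roi} AUC condition x period"))
            for e in effects:
                lines.append(
                    f"- {roi} AUC {e.name}: F({e.df_num}, {e.df_den}) = "
                    f"{e.F:.2f}, p = {e.p:.4g}"
                )
        except ValueError as err:
            lines.append(f"- {roi} AUC ANOVA skipped ({err})")
        blocks = metrics[(metrics["roi"] == roi) & (metrics["block"] > 0)]
        if blocks["block"].nunique() >= 2:
            blong = blocks.melt(
                id_vars=["subject", "condition", "block"],
                value_vars=["auc_pre", "auc_post"],
                var_name="period",
                value_name="auc",
            )
            try:
                effects = rm_anova(
                    blong, dv="auc", within=["block", "condition", "period"]
                )
                frames.append(_effects_frame(effects, f"{roi} AUC block x cond x period"))
                raws = []
                for b in sorted(blocks["block"].unique()):
                    for period in ("auc_pre", "auc_post"):
                        w = blocks[blocks["block"] == b].pivot(
                            index="subject", columns="condition", values=period
                        ).dropna()
                        if {"high", "neutral"} <= set(w.columns) and len(w) >= 2:
                            raws.append(
                                (b, period, paired_t(w["high"].to_numpy(), w["neutral"].to_numpy()))
                            )
                adj = bonferroni([r.p for *_, r in raws], len(raws))
                for (b, period, res), pa in zip(raws, adj):
                    lines.append(
                        f"  - {roi} block {b} {period}: t({res.df}) = {res.t:.2f}, "
                        f"p_bonf = {pa:.4g}"
                    )
            except ValueError as err:
                lines.append(f"- {roi} blockwise ANOVA skipped ({err})")

    for roi in sensory_rois:
        sub = session[session["roi"] == roi]
        w = sub.pivot(index="subject", columns="condition", values="auc_reveal")
        if {"high", "neutral"} <= set(w.columns):
            res = paired_t(w["high"].to_numpy(), w["neutral"].to_numpy())
            lines.append(
                f"- {roi} reveal AUC: t({res.df}) = {res.t:.2f}, p = {res.p:.4g} "
                f"(mean diff {res.mean_diff:+.3f})"
            )
    stats_df = (
        pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    )
    return stats_df, "\n".join(lines) + "\n"


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate, analyse and report a full study into ``out_dir``."""
    out = Path(out_dir)
    for sub in ("events", "series", "confounds", "stats", "figures"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    metric_frames = []
    rt_rows = []
    profiles_all: dict[str, dict[str, list[ConditionProfile]]] = {}
    block_profiles: dict[int, dict[str, list[ConditionProfile]]] = {}
    step_rois = [r for r, k in config.rois.items() if k is ProfileKind.STEP]

    for i, child in enumerate(root.spawn(config.n_subjects)):
        rng = np.random.default_rng(child)
        name = f"sub-{i + 1:02d}"
        gt = config.ground_truth
        if config.subject_jitter > 0:
            gain = rng.uniform(1 - config.subject_jitter, 1 + config.subject_jitter)
            gt = gt.scaled(drift_factor=gain, threshold_factor=gain)
        data = simulate_subject(gt, config.paradigm, config.rois, rng=rng, subject=name)
        write_events(data.events, out / "events" / f"{name}.tsv")
        write_series(data.series, out / "series" / f"{name}.tsv")
        write_confounds(data.confounds, out / "confounds" / f"{name}.tsv")
        if config.write_nifti:
            from .io import write_series_nifti

            write_series_nifti(data.series, out / "series" / f"{name}-nifti")

        resid = regress_confounds(data.series, data.confounds)
        ev = filter_correct(data.events)
        epochs = epoch_trials(resid, ev, shift_s=config.shift_s, subject=name)
        surviving = {e.trial_id for e in epochs}
        ev = ev.loc[ev.index.isin(surviving)]
        profs, trials_by_cond = fit_condition_profiles(
            epochs, ev, tr=config.paradigm.tr, subject=name
        )
        rows = [
            condition_metrics(
                p,
                trials_by_cond[cond],
                reveal_duration=config.paradigm.reveal_duration,
                peak_window=config.peak_window,
            )
            for (roi, cond), p in profs.items()
        ]
        metrics = pd.DataFrame(rows)
        if config.compute_blocks:
            metrics = pd.concat(
                [
                    metrics,
                    blockwise_metrics(
                        trials_by_cond,
                        reveal_duration=config.paradigm.reveal_duration,
                        peak_window=config.peak_window,
                        subject=name,
                    ),
                ],
                ignore_index=True,
            )
        metric_frames.append(metrics)
        for (roi, cond), p in profs.items():
            profiles_all.setdefault(roi, {}).setdefault(cond, []).append(p)
        # Per-block step-ROI profiles for the habituation figure.
        for roi in step_rois:
            for cond, trials in trials_by_cond.items():
                from .profiles import fir_fit

                for b in sorted({run_block(t.run) for t in trials}):
                    sel = [t for t in trials if run_block(t.run) == b]
                    if not sel:
                        continue
                    bp = fir_fit(
                        sel, cond, mean_rt=sel[0].pre_len * sel[0].tr, subject=name
                    )[roi]
                    block_profiles.setdefault(b, {}).setdefault(cond, []).append(bp)
        for cond, grp in ev.groupby("trial_type"):
            rt_rows.append(
                {
                    "subject": name,
                    "condition": cond,
                    "mean_rt": grp["response_time"].mean(),
                }
            )

    metrics = pd.concat(metric_frames, ignore_index=True)
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.6f")
    write_ground_truth(config.ground_truth, out / "ground_truth.yaml", config.paradigm)

    # Behavioural paired t-test on condition mean RTs.
    rt = pd.DataFrame(rt_rows).pivot(index="subject", columns="condition", values="mean_rt")
    stats_lines = []
    if {"high", "neutral"} <= set(rt.columns):
        res = paired_t(rt["high"].to_numpy(), rt["neutral"].to_numpy())
        stats_lines.append(
            f"- behaviour: RT high - neutral = {res.mean_diff:+.2f} s, "
            f"t({res.df}) = {res.t:.2f}, p = {res.p:.4g}"
        )
    stats_df, report = _group_stats(metrics, config)
    report = report + "\n".join(stats_lines) + "\n"
    if not stats_df.empty:
        stats_df.to_csv(out / "stats" / "effects.tsv", sep="\t", index=False, float_format="%.6g")
    (out / "stats" / "report.md").write_text(report)

    from .plots import plot_block_profiles, plot_condition_profiles

    group_profiles = {
        roi: [
            p
            for cond in sorted(by_cond)
            if (p := _mean_profile(by_cond[cond])) is not None
        ]
        for roi, by_cond in profiles_all.items()
    }
    plot_condition_profiles(
        group_profiles,
        out / "figures" / "condition_profiles.png",
        reveal_end=config.paradigm.reveal_duration,
    )
    for roi in step_rois:
        by_block = {
            b: [
                p
                for cond in sorted(by_cond)
                if (p := _mean_profile(by_cond[cond])) is not None
            ]
            for b, by_cond in block_profiles.items()
        }
        if by_block:
            plot_block_profiles(
                by_block,
                out / "figures" / f"{roi}_blocks.png",
                roi=roi,
                reveal_end=config.paradigm.reveal_duration,
            )

    manifest = {
        "gradreveal_version": __version__,
        "seed": config.seed,
        "config_sha256_16": config_hash(config),
    }
    import yaml as _yaml

    (out / "config.yaml").write_text(
        resolved_yaml(config) + "\n# manifest\n" + _yaml.safe_dump(manifest)
    )
    return out


def make_fixtures(seed: int, out_dir: str | Path) -> dict:
    """Write a small frozen bundle (2 subjects, 2 runs, 12 trials).

    Returns a manifest dict with per-file SHA-256 checksums; the bundle
    regenerates bit-identically from the same seed.
    """
    from .synth import GroundTruth, ParadigmConfig

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paradigm = ParadigmConfig(n_runs=2, n_trials_total=12)
    gt = GroundTruth(seed=seed)
    rois = {"acc": ProfileKind.ACCUMULATOR, "amygdala": ProfileKind.STEP}
    root = np.random.SeedSequence(seed)
    files: dict[str, str] = {}
    for i, child in enumerate(root.spawn(2)):
        name = f"sub-{i + 1:02d}"
        data = simulate_subject(
            gt, paradigm, rois, rng=np.random.default_rng(child), subject=name
        )
        for kind, writer, obj in (
            ("events", write_events, data.events),
            ("series", write_series, data.series),
            ("confounds", write_confounds, data.confounds),
        ):
            p = out / f"{name}_{kind}.tsv"
            writer(obj, p)
            files[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    write_ground_truth(gt, out / "ground_truth.yaml", paradigm)
    files["ground_truth.yaml"] = hashlib.sha256(
        (out / "ground_truth.yaml").read_bytes()
    ).hexdigest()
    manifest = {"seed": seed, "files": files}
    import yaml as _yaml

    (out / "manifest.yaml").write_text(_yaml.safe_dump(manifest, sort_keys=True))
    return manifest
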