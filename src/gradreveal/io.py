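"""Reading and writing the pipeline's on-disk formats.

Events travel as BIDS-style TSV (tab-separated, ``.`` decimal, ``n/a``
for missing values); ROI series and confounds as TSV with one header
row; ground truth and run configuration as YAML; ROI series optionally
as 4D NIfTI plus per-ROI binary mask NIfTI for interoperability with
imaging tools.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ConditionProfile,
    InterpolatedTrial,
    RoiTimeSeries,
    TrialEpoch,
    validate_events,
)
from .synth import GroundTruth, ParadigmConfig

__all__ = [
    "write_events",
    "read_events",
    "write_series",
    "read_series",
    "write_confounds",
    "read_confounds",
    "write_ground_truth",
    "read_ground_truth",
    "write_series_nifti",
    "read_series_nifti",
    "write_epochs",
    "read_epochs",
    "write_trials",
    "read_trials",
    "write_profiles",
    "read_profiles",
]

_NA = "n/a"
_FLOAT_FMT = "%.6f"


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    """Write a BIDS-style events TSV (``n/a`` for missing values)."""
    path = Path(path)
    validate_events(events)
    events.to_csv(path, sep="\t", index=False, na_rep=_NA, float_format=_FLOAT_FMT)
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)
    return validate_events(events)


def write_series(series: RoiTimeSeries, path: str | Path) -> Path:
    """ROI series as TSV: header = ROI names plus a ``run`` column."""
    path = Path(path)
    df = pd.DataFrame(series.values, columns=list(series.roi_names))
    df["run"] = series.run_index
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")
    return path


def read_series(path: str | Path, tr: float) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    if "run" in df.columns:
        run_index = df.pop("run").to_numpy(dtype=int)
    else:
        run_index = np.ones(len(df), dtype=int)
    return RoiTimeSeries(
        values=df.to_numpy(dtype=float),
        roi_names=tuple(df.columns),
        tr=tr,
        run_index=run_index,
    )


def write_confounds(confounds: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    confounds.to_csv(path, sep="\t", index=False, na_rep=_NA, float_format="%.8f")
    return path


def read_confounds(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False)


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_ground_truth(
    ground_truth: GroundTruth, path: str | Path, paradigm: ParadigmConfig | None = None
) -> Path:
    """YAML sidecar with the generating parameters, for recovery tests."""
    path = Path(path)
    payload = {"ground_truth": _as_plain(dataclasses.asdict(ground_truth))}
    if paradigm is not None:
        payload["paradigm"] = _as_plain(dataclasses.asdict(paradigm))
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_ground_truth(path: str | Path) -> tuple[GroundTruth, ParadigmConfig | None]:
    payload = yaml.safe_load(Path(path).read_text())
    gt_kwargs = dict(payload["ground_truth"])
    for key in ("iti_choices",):
        gt_kwargs.pop(key, None)
    gt = GroundTruth(**gt_kwargs)
    paradigm = None
    if "paradigm" in payload:
        pkw = dict(payload["paradigm"])
        pkw["iti_choices"] = tuple(pkw.get("iti_choices", (6.0, 8.0, 10.0)))
        paradigm = ParadigmConfig(**pkw)
    return gt, paradigm


def write_series_nifti(series: RoiTimeSeries, directory: str | Path) -> dict[str, Path]:
    """Emit the ROI series as 4D NIfTI plus one binary mask per ROI.

    Each ROI occupies one voxel along the x axis of a minimal volume;
    this is an interoperability format, not a spatial simulation.
    """
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n_rois = series.n_rois
    data = np.zeros((n_rois, 1, 1, series.n_samples), dtype=np.float32)
    for j in range(n_rois):
        data[j, 0, 0, :] = series.values[:, j]
    affine = np.eye(4)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, series.tr))
    paths = {"bold": directory / "bold.nii"}
    nib.save(img, paths["bold"])
    for j, roi in enumerate(series.roi_names):
        mask = np.zeros((n_rois, 1, 1), dtype=np.uint8)
        mask[j, 0, 0] = 1
        p = directory / f"mask-{roi}.nii"
        nib.save(nib.Nifti1Image(mask, affine), p)
        paths[roi] = p
    return paths


def read_series_nifti(
    bold_path: str | Path,
    mask_paths: dict[str, str | Path],
    tr: float,
    run_index: np.ndarray | None = None,
) -> RoiTimeSeries:
    """Extract mean in-mask voxel time series per ROI from 4D NIfTI."""
    import nibabel as nib

    img = nib.load(str(bold_path))
    data = np.asarray(img.dataobj, dtype=float)
    n_samples = data.shape[-1]
    cols = []
    names = []
    for roi, mpath in mask_paths.items():
        mask = np.asarray(nib.load(str(mpath)).dataobj) > 0
        if not mask.any():
            raise ValueError(f"mask for ROI {roi!r} is empty")
        cols.append(data[mask].mean(axis=0))
        names.append(roi)
    if run_index is None:
        run_index = np.ones(n_samples, dtype=int)
    return RoiTimeSeries(
        values=np.column_stack(cols),
        roi_names=tuple(names),
        tr=tr,
        run_index=run_index,
    )


def write_epochs(epochs: list[TrialEpoch], path: str | Path) -> Path:
    """Trial epochs in long TSV form (one row per trial x segment x sample x ROI)."""
    rows = []
    for e in epochs:
        for seg_name, seg in (("pre", e.pre), ("post", e.post)):
            for idx in range(seg.shape[0]):
                for j, roi in enumerate(e.roi_names):
                    rows.append(
                        (e.subject, e.trial_id, e.condition, e.run, e.rt, e.tr,
                         roi, seg_name, idx, seg[idx, j])
                    )
    df = pd.DataFrame(
        rows,
        columns=["subject", "trial_id", "condition", "run", "rt", "tr",
                 "roi", "segment", "idx", "value"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")
    return Path(path)


def read_epochs(path: str | Path) -> list[TrialEpoch]:
    df = pd.read_csv(path, sep="\t")
    epochs = []
    for (subject, trial_id), grp in df.groupby(["subject", "trial_id"], sort=True):
        rois = tuple(dict.fromkeys(grp["roi"]))
        segs = {}
        for seg_name, sgrp in grp.groupby("segment"):
            wide = sgrp.pivot(index="idx", columns="roi", values="value")
            segs[seg_name] = wide[list(rois)].to_numpy()
        first = grp.iloc[0]
        epochs.append(
            TrialEpoch(
                trial_id=int(trial_id),
                condition=str(first["condition"]),
                pre=segs["pre"],
                post=segs["post"],
                rt=float(first["rt"]),
                run=int(first["run"]),
                roi_names=rois,
                tr=float(first["tr"]),
                subject=str(subject),
            )
        )
    return epochs


def write_trials(trials: list[InterpolatedTrial], path: str | Path) -> Path:
    """Interpolated (common-grid, zero-locked) trials in long TSV form."""
    rows = []
    for t in trials:
        for b in range(t.values.shape[0]):
            for j, roi in enumerate(t.roi_names):
                rows.append(
                    (t.subject, t.trial_id, t.condition, t.run, t.rt, t.tr,
                     t.pre_len, roi, b, t.values[b, j])
                )
    df = pd.DataFrame(
        rows,
        columns=["subject", "trial_id", "condition", "run", "rt", "tr",
                 "pre_len", "roi", "bin", "value"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")
    return Path(path)


def read_trials(path: str | Path) -> list[InterpolatedTrial]:
    df = pd.read_csv(path, sep="\t")
    trials = []
    for (subject, trial_id), grp in df.groupby(["subject", "trial_id"], sort=True):
        rois = tuple(dict.fromkeys(grp["roi"]))
        wide = grp.pivot(index="bin", columns="roi", values="value")
        first = grp.iloc[0]
        trials.append(
            InterpolatedTrial(
                trial_id=int(trial_id),
                condition=str(first["condition"]),
                values=wide[list(rois)].to_numpy(),
                pre_len=int(first["pre_len"]),
                zero_ref=np.zeros(len(rois)),
                roi_names=rois,
                tr=float(first["tr"]),
                run=int(first["run"]),
                rt=float(first["rt"]),
                subject=str(subject),
            )
        )
    return trials


def write_profiles(profiles: list[ConditionProfile], path: str | Path) -> Path:
    """Condition profiles as tidy TSV (subject, roi, condition, bin, time_s, coefficient)."""
    rows = []
    for p in profiles:
        for b, (t, c) in enumerate(zip(p.times, p.coef)):
            rows.append(
                (p.subject, p.roi, p.condition, b, t, c, p.n_trials, p.mean_rt,
                 p.tr, p.pre_len)
            )
    df = pd.DataFrame(
        rows,
        columns=["subject", "roi", "condition", "bin", "time_s", "coefficient",
                 "n_trials", "mean_rt", "tr", "pre_len"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8f")
    return Path(path)


def read_profiles(path: str | Path) -> list[ConditionProfile]:
    df = pd.read_csv(path, sep="\t")
    out = []
    keys = ["subject", "roi", "condition"]
    for (subject, roi, condition), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("bin")
        first = grp.iloc[0]
        out.append(
            ConditionProfile(
                subject=str(subject),
                roi=str(roi),
                condition=str(condition),
                coef=grp["coefficient"].to_numpy(),
                n_trials=int(first["n_trials"]),
                mean_rt=float(first["mean_rt"]),
                tr=float(first["tr"]),
                pre_len=int(first["pre_len"]),
            )
        )
    return out
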