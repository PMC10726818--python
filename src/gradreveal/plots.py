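"""Profile figures: per-ROI condition time courses with decision markers."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .containers import ConditionProfile

__all__ = ["plot_condition_profiles", "plot_block_profiles"]

_COND_COLORS = {"neutral": "tab:blue", "high": "tab:red"}


def _draw_profiles(ax, profiles: Sequence[ConditionProfile], reveal_end: float) -> None:
    for prof in profiles:
        color = _COND_COLORS.get(prof.condition, "tab:gray")
        ax.plot(prof.times, prof.coef, color=color, label=f"{prof.condition}")
        ax.axvline(prof.mean_rt, color=color, linestyle="--", linewidth=0.8)
    ax.axvline(reveal_end, color="black", linewidth=1.0)
    ax.axhline(0.0, color="0.7", linewidth=0.5)
    ax.set_xlabel("trial time (s)")
    ax.set_ylabel("FIR coefficient (z)")


def plot_condition_profiles(
    profiles_by_roi: Mapping[str, Sequence[ConditionProfile]],
    out_path: str | Path,
    reveal_end: float = 25.0,
) -> Path:
    """One panel per ROI; dashed vertical lines mark the condition mean
    decision times, the solid black line the end of the gradual reveal."""
    out_path = Path(out_path)
    rois = list(profiles_by_roi)
    fig, axes = plt.subplots(
        1, len(rois), figsize=(4 * len(rois), 3.2), squeeze=False, sharey=False
    )
    for ax, roi in zip(axes[0], rois):
        _draw_profiles(ax, profiles_by_roi[roi], reveal_end)
        ax.set_title(roi)
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path


def plot_block_profiles(
    profiles_by_block: Mapping[int, Sequence[ConditionProfile]],
    out_path: str | Path,
    roi: str,
    reveal_end: float = 25.0,
) -> Path:
    """One panel per scan block for a single ROI (habituation view)."""
    out_path = Path(out_path)
    blocks = sorted(profiles_by_block)
    fig, axes = plt.subplots(
        1, len(blocks), figsize=(4 * len(blocks), 3.2), squeeze=False, sharey=True
    )
    for ax, b in zip(axes[0], blocks):
        _draw_profiles(ax, profiles_by_block[b], reveal_end)
        ax.set_title(f"{roi} - block {b}")
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    return out_path
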