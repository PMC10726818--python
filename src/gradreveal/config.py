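"""Run configuration: YAML schema for end-to-end reproducible runs."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synth import GroundTruth, ParadigmConfig, ProfileKind

__all__ = ["RunConfig", "load_config", "resolved_yaml"]

#: Default ROI archetype layout of a full simulated study.
DEFAULT_ROIS = {
    "loc": "accumulator",
    "acc_insula": "moment_of_decision",
    "occ_pole": "sensory",
    "amygdala": "step",
}


@dataclass
class RunConfig:
    """Validated configuration of a full simulate-and-analyse run."""

    seed: int = 0
    n_subjects: int = 8
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    ground_truth: GroundTruth = field(default_factory=GroundTruth)
    rois: dict[str, ProfileKind] = field(
        default_factory=lambda: {k: ProfileKind(v) for k, v in DEFAULT_ROIS.items()}
    )
    shift_s: float = 5.0
    peak_window: float = 3.0
    grid_policy: str = "subject"
    subject_jitter: float = 0.0
    alpha: float = 0.05
    compute_blocks: bool = True
    write_nifti: bool = False

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.grid_policy not in ("subject", "group"):
            raise ValueError("grid_policy must be 'subject' or 'group'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.shift_s < 0 or self.peak_window <= 0:
            raise ValueError("shift_s must be >= 0 and peak_window > 0")
        self.rois = {r: ProfileKind(k) for r, k in self.rois.items()}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update(overrides)
    kwargs: dict = {}
    if "paradigm" in raw:
        pkw = dict(raw.pop("paradigm"))
        if "iti_choices" in pkw:
            pkw["iti_choices"] = tuple(pkw["iti_choices"])
        kwargs["paradigm"] = ParadigmConfig(**pkw)
    if "ground_truth" in raw:
        kwargs["ground_truth"] = GroundTruth(**raw.pop("ground_truth"))
    if "rois" in raw:
        kwargs["rois"] = {r: ProfileKind(k) for r, k in raw.pop("rois").items()}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    kwargs.update(raw)
    return RunConfig(**kwargs)


def resolved_yaml(config: RunConfig) -> str:
    """Serialize the resolved configuration (for the run manifest)."""

    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return plain(dataclasses.asdict(obj))
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, ProfileKind):
            return obj.value
        if hasattr(obj, "item"):
            return obj.item()
        return obj

    return yaml.safe_dump(plain(config), sort_keys=False)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(resolved_yaml(config).encode()).hexdigest()[:16]
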