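"""Tunable parameters for every pipeline stage, with YAML override support.

All defaults that are genuinely free choices (the source assay never pins
them down) live here so a single config file documents the full behaviour
of a deployment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class OrbParams:
    """ORB detector settings: oriented FAST-9 corners + 256-bit rBRIEF."""

    n_keypoints: int = 500
    fast_n: int = 9           # FAST circular radius (FAST-9)
    fast_threshold: float = 0.08
    n_scales: int = 8
    downscale: float = 1.2


@dataclass
class RegistrationParams:
    orb: OrbParams = field(default_factory=OrbParams)
    ransac_threshold_px: float = 3.0
    max_iters: int = 2000
    min_inliers: int = 10


@dataclass
class WindowGeometry:
    """Histogram-window placement relative to a strip-label bounding box.

    The window hangs below the label's bottom-middle point: narrower than
    the label (to dodge strip-edge shadows), starting ``gap_factor`` label
    heights below it and extending ``length_factor`` label heights down.
    """

    width_factor: float = 0.6
    gap_factor: float = 0.2
    length_factor: float = 2.5


@dataclass
class SegmentationParams:
    closing_size: int = 3
    column_min_fraction: float = 0.10
    # How the two alcohol-case channel conjunctions (G&B, G&R) are merged.
    alcohol_combination: str = "union"  # "union" | "intersection"
    window: WindowGeometry = field(default_factory=WindowGeometry)


@dataclass
class HistogramParams:
    n_bins: int = 100          # resampling target for line strips
    n_bins_final: int = 62     # aligned output length (2 x 31)
    half_window: int = 15      # +-15 bins kept around each minimum
    n_av: int = 15             # leading bins averaged for alcohol offset
    baseline_threshold_frac: float = 0.05  # RANSAC inlier band, fraction of range
    baseline_max_trials: int = 500
    alcohol_baseline: bool = False  # alcohol path skips baseline removal
    channel: str = "luminance"


@dataclass
class TrainerParams:
    learning_rate: float = 0.02
    max_epochs: int = 4000
    patience: int = 300
    l2: float = 1e-4                 # weight decay; keeps margins sane
    class_weight: str | None = "balanced"


@dataclass
class PipelineParams:
    # What a "doubtful" test-line class means for the reported result.
    doubtful_policy: str = "undetermined"  # "undetermined" | "positive" | "negative"


@dataclass
class ReaderConfig:
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    histogram: HistogramParams = field(default_factory=HistogramParams)
    trainer: TrainerParams = field(default_factory=TrainerParams)
    pipeline: PipelineParams = field(default_factory=PipelineParams)


def _update(obj, overrides: dict):
    for key, value in overrides.items():
        if not hasattr(obj, key):
            raise KeyError(f"unknown config key: {key!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _update(current, value)
        else:
            setattr(obj, key, value)


def load_config(path: str | Path | None = None) -> ReaderConfig:
    """Build a :class:`ReaderConfig`, optionally overridden from a YAML file.

    The YAML mirrors the dataclass nesting, e.g.::

        segmentation:
          alcohol_combination: intersection
          window: {width_factor: 0.5}
    """
    cfg = ReaderConfig()
    if path is not None:
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        _update(cfg, overrides)
    return cfg
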