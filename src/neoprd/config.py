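"""Run configuration for the whole pipeline.

All tunable constants live here with their defaults; the values mirror the
processing rules of the study protocol (INVOS floor 15 %, SpO2 minimum 20 %,
4 %/s jump rule, 30 s collar, 10 Hz upsampling, 1/6 Hz target grid, 4 h
epochs with 50 % overlap, 63 %/85 % hypoxia thresholds, 0.4 decision
threshold). A single ``seed`` fans out deterministically to every random
component (cohort generation, bootstraps, model fits).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # --- preprocessing ---
    rcso2_floor: float = 15.0          # % — INVOS saturates here when the probe detaches
    spo2_min: float = 20.0             # % — SpO2 readings below this are artifact
    spo2_jump: float = 4.0             # %/s — faster changes are artifact
    collar_s: float = 30.0             # s removed on each side of a flagged sample
    upsample_fs: float = 10.0          # Hz, intermediate grid for interpolation
    target_fs: float = 1.0 / 6.0       # Hz, analysis grid
    gap_tolerance_factor: float = 2.0  # gaps > factor x nominal period are invalidated

    # --- epoching ---
    epoch_hours: float = 4.0
    overlap: float = 0.5
    min_valid_fraction: float = 0.75

    # --- thresholds ---
    rcso2_threshold: float = 63.0      # % — time-below comparator for rcSO2
    spo2_threshold: float = 85.0       # % — time-below comparator for SpO2
    decision_threshold: float = 0.4    # probability >= this is a positive call
    detect_threshold: float = 3.0      # % — desaturation-component excursion depth

    # --- evaluation ---
    n_boot: int = 1000
    ci_level: float = 0.95

    seed: int = 0

    def __post_init__(self) -> None:
        if self.collar_s < 0:
            raise ValueError("collar must be >= 0")
        if not 0 < self.overlap < 1:
            raise ValueError("overlap must be in (0, 1)")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision threshold must be in (0, 1)")

    @property
    def epoch_step_hours(self) -> float:
        return self.epoch_hours * (1.0 - self.overlap)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
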