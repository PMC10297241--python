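"""The 14-feature per-recording descriptor of the extracted PRD component.

Features: event rate per hour, total power of the PRD component, envelope
mean and SD, the three Hjorth parameters (activity, mobility, complexity),
inter-event interval mean and SD (nadir to nadir), time spent below the
hypoxia threshold (63 % rcSO2 / 85 % SpO2, measured on the original
signal), and event-averaged morphology: nadir amplitude, downward slope,
upward slope and duration.

Zero-event recordings keep a genuine zero rate and power but leave the
morphology features missing — zero-filling would fabricate "zero-depth
events"; the tree learners handle missing values natively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .epoch_features import envelope
from .prd import PRDDecomposition, PRDEvent
from .preprocess import UniformSignal

__all__ = [
    "PRDFeatureVector",
    "PRD_FEATURE_NAMES",
    "hjorth",
    "time_below_threshold",
    "compute_prd_features",
]


@dataclass
class PRDFeatureVector:
    rate_per_hour: float
    total_power: float
    env_mean: float
    env_sd: float
    hjorth_activity: float
    hjorth_mobility: float
    hjorth_complexity: float
    isi_mean: float            # s
    isi_sd: float              # s
    time_below_threshold: float  # h, on the original signal
    nadir_amp_mean: float      # %
    slope_down_mean: float     # %/min
    slope_up_mean: float       # %/min
    duration_mean: float       # s

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in fields(self)})


PRD_FEATURE_NAMES = [f.name for f in fields(PRDFeatureVector)]


def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth parameters (activity, mobility, complexity).

    activity = var(x); mobility = sqrt(var(dx)/var(x)) with dx the first
    difference (per-sample units); complexity = mobility(dx)/mobility(x).
    A constant series has zero activity and undefined mobility.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples for Hjorth parameters")
    activity = float(np.var(x))
    if activity == 0:
        raise ValueError("Hjorth parameters undefined for a constant series (zero activity)")
    d1 = np.diff(x)
    d2 = np.diff(d1)
    v1 = np.var(d1)
    mobility = float(np.sqrt(v1 / activity))
    if v1 == 0:
        raise ValueError("Hjorth complexity undefined (constant first difference)")
    complexity = float(np.sqrt(np.var(d2) / v1) / mobility)
    return activity, mobility, complexity


def time_below_threshold(sig: UniformSignal, threshold: float) -> float:
    """Hours of valid signal strictly below ``threshold`` %."""
    below = sig.valid_mask & (sig.values < threshold)
    return float(below.sum() / sig.fs / 3600.0)


def compute_prd_features(
    events: list[PRDEvent],
    dec: PRDDecomposition,
    threshold: float,
) -> PRDFeatureVector:
    """The 14-feature vector for one recording/channel.

    Rate normalises by the valid recording hours. Power, envelope and
    Hjorth parameters are computed on the PRD component over valid
    samples; inter-event intervals are nadir-to-nadir.
    """
    sig = dec.original
    valid = sig.valid_mask
    hours = sig.valid_hours
    prd_valid = dec.prd_component[valid]

    rate = len(events) / hours if hours > 0 else np.nan
    power = float(np.mean(prd_valid**2)) if len(prd_valid) else 0.0

    if len(prd_valid) >= 3 and np.ptp(prd_valid) > 0:
        env = envelope(dec.prd_component)[valid]
        env_mean, env_sd = float(env.mean()), float(env.std(ddof=1))
        try:
            act, mob, comp = hjorth(prd_valid)
        except ValueError:
            act = mob = comp = np.nan
    else:
        env_mean = env_sd = np.nan
        act = mob = comp = np.nan

    nadirs = np.array([ev.nadir_time for ev in events])
    if len(nadirs) >= 2:
        isi = np.diff(np.sort(nadirs))
        isi_mean, isi_sd = float(isi.mean()), float(isi.std(ddof=1)) if len(isi) > 1 else np.nan
    else:
        isi_mean = isi_sd = np.nan

    if events:
        nadir_amp = float(np.mean([ev.nadir_amplitude for ev in events]))
        slope_down = float(np.nanmean([ev.slope_down for ev in events]))
        slope_up = float(np.nanmean([ev.slope_up for ev in events]))
        duration = float(np.mean([ev.duration for ev in events]))
    else:
        nadir_amp = slope_down = slope_up = duration = np.nan

    return PRDFeatureVector(
        rate_per_hour=rate,
        total_power=power,
        env_mean=env_mean,
        env_sd=env_sd,
        hjorth_activity=act,
        hjorth_mobility=mob,
        hjorth_complexity=comp,
        isi_mean=isi_mean,
        isi_sd=isi_sd,
        time_below_threshold=time_below_threshold(sig, threshold),
        nadir_amp_mean=nadir_amp,
        slope_down_mean=slope_down,
        slope_up_mean=slope_up,
        duration_mean=duration,
    )
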