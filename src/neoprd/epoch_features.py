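"""Per-epoch quantitative features of a uniform saturation signal.

The signal is split into a 5-band dyadic filter bank (zero-phase FIR) and,
for every 4-h epoch (50 % overlap) and band, 13 features are computed:
four envelope statistics (mean, SD, 5th/95th percentiles), signal skewness
and kurtosis, six instantaneous-frequency statistics (mean, SD, skewness,
kurtosis, 5th/95th percentiles), and the Higuchi fractal dimension.
Together with the postnatal age at the epoch midpoint this yields 66
features per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin, hilbert
from scipy.stats import kurtosis, skew

from .preprocess import UniformSignal

__all__ = [
    "FilterBankSpec",
    "EpochSpec",
    "dyadic_filter_bank",
    "envelope",
    "instantaneous_frequency",
    "higuchi_fd",
    "extract_epoch_features",
    "FEATURE_COLUMNS",
]

N_BANDS = 5

_BAND_STATS = [
    "env_mean", "env_sd", "env_p5", "env_p95",
    "skew", "kurt",
    "if_mean", "if_sd", "if_skew", "if_kurt", "if_p5", "if_p95",
    "fd",
]

#: the 66 feature columns, in canonical order
FEATURE_COLUMNS = [
    f"b{b}_{stat}" for b in range(N_BANDS) for stat in _BAND_STATS
] + ["postnatal_age_h"]


@dataclass
class FilterBankSpec:
    """Dyadic filter bank: 5 zero-phase FIR filters of bandwidth a/2^b,
    a = fs/2, b = 0..4.

    The printed bandwidth formula is read as nested low-pass filters with
    cutoffs fs/2, fs/4, ... fs/64 (band 0 is all-pass); set
    ``mode="octave-bandpass"`` for the octave band-pass tiling reading.
    """

    fs: float = 1.0 / 6.0
    numtaps: int = 601
    window: str = "hamming"
    mode: str = "nested-lowpass"

    def __post_init__(self) -> None:
        if self.mode not in ("nested-lowpass", "octave-bandpass"):
            raise ValueError(f"unknown filter-bank mode {self.mode!r}")
        if self.numtaps % 2 == 0:
            raise ValueError("numtaps must be odd for exact zero phase")

    @property
    def a(self) -> float:
        return self.fs / 2.0

    def bandwidths(self) -> list[float]:
        return [self.a / 2**b for b in range(N_BANDS)]


def _zero_phase_fir(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Single-pass symmetric FIR with reflection padding and delay
    compensation: exactly zero phase, gain applied once."""
    half = len(taps) // 2
    pad = min(half, len(x) - 1)
    padded = np.concatenate([x[pad:0:-1], x, x[-2:-2 - pad:-1]])
    return fftconvolve(padded, taps, mode="same")[pad:pad + len(x)]


def dyadic_filter_bank(sig: UniformSignal | np.ndarray, spec: FilterBankSpec | None = None) -> list[np.ndarray]:
    """Apply the 5-filter dyadic bank; returns one signal per band."""
    spec = spec or FilterBankSpec()
    x = sig.values if isinstance(sig, UniformSignal) else np.asarray(sig, dtype=float)
    if len(x) < 3 * spec.numtaps:
        raise ValueError(
            f"signal of {len(x)} samples shorter than 3x filter order ({3 * spec.numtaps})"
        )
    nyq = spec.fs / 2.0
    out: list[np.ndarray] = []
    for b in range(N_BANDS):
        bw = spec.a / 2**b
        if spec.mode == "nested-lowpass":
            if b == 0:
                out.append(x.copy())   # cutoff at Nyquist: all-pass
                continue
            taps = firwin(spec.numtaps, bw / nyq, window=spec.window)
        else:
            hi = spec.a / 2**b
            lo = hi / 2.0
            if b == N_BANDS - 1:
                taps = firwin(spec.numtaps, hi / nyq, window=spec.window)
            else:
                taps = firwin(spec.numtaps, [lo / nyq, min(hi / nyq, 0.999)],
                              window=spec.window, pass_zero=False)
        out.append(_zero_phase_fir(x, taps))
    return out


def envelope(x: np.ndarray) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic signal of the
    mean-removed series, plus the mean (so a constant c has envelope |c|)."""
    x = np.asarray(x, dtype=float)
    mu = x.mean()
    return np.abs(hilbert(x - mu)) + mu


def instantaneous_frequency(x: np.ndarray, fs: float) -> np.ndarray:
    """Instantaneous frequency (Hz) from a central finite difference of
    the unwrapped analytic-signal phase; one-sided at the endpoints.

    Raises on a constant series, where the phase is undefined.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("instantaneous frequency undefined for a constant series")
    phase = np.unwrap(np.angle(hilbert(x - x.mean())))
    # np.gradient: central differences interior, one-sided at the ends
    return np.gradient(phase) * fs / (2.0 * np.pi)


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension of a series, in [1, 2].

    Curve lengths L(k) are computed for delays k = 1..kmax and the FD is
    the slope of log L(k) against log(1/k). Requires at least 10*kmax
    samples for a stable fit.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 * kmax:
        raise ValueError(f"series of {n} samples too short for kmax={kmax}")
    lengths = np.empty(kmax)
    for k in range(1, kmax + 1):
        lk = 0.0
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (len(idx) - 1) / k
            lk += dist * norm / k
        lengths[k - 1] = lk / k
    k_arr = np.arange(1, kmax + 1)
    good = lengths > 0
    if good.sum() < 2:
        return 1.0  # flat line: zero curve length at every scale
    slope = np.polyfit(np.log(1.0 / k_arr[good]), np.log(lengths[good]), 1)[0]
    return float(slope)


@dataclass
class EpochSpec:
    """Epoching: 4-h windows stepping by 2 h (50 % overlap)."""

    epoch_hours: float = 4.0
    overlap: float = 0.5
    min_valid_fraction: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.overlap < 1:
            raise ValueError("overlap must be in (0, 1)")

    @property
    def step_hours(self) -> float:
        return self.epoch_hours * (1.0 - self.overlap)


def _band_features(x: np.ndarray, fs: float) -> dict:
    env = envelope(x)
    feats = {
        "env_mean": env.mean(),
        "env_sd": env.std(ddof=1),
        "env_p5": np.percentile(env, 5),
        "env_p95": np.percentile(env, 95),
        "skew": skew(x),
        "kurt": kurtosis(x, fisher=False),
    }
    try:
        inst_f = instantaneous_frequency(x, fs)
        feats.update(
            if_mean=inst_f.mean(),
            if_sd=inst_f.std(ddof=1),
            if_skew=skew(inst_f),
            if_kurt=kurtosis(inst_f, fisher=False),
            if_p5=np.percentile(inst_f, 5),
            if_p95=np.percentile(inst_f, 95),
        )
    except ValueError:   # flat epoch
        feats.update({k: np.nan for k in ("if_mean", "if_sd", "if_skew",
                                          "if_kurt", "if_p5", "if_p95")})
    try:
        feats["fd"] = higuchi_fd(x)
    except ValueError:
        feats["fd"] = np.nan
    return feats


def extract_epoch_features(
    sig: UniformSignal,
    espec: EpochSpec | None = None,
    fspec: FilterBankSpec | None = None,
    values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Compute the 66-feature matrix of one signal.

    One row per 4-h epoch; epochs with fewer than ``min_valid_fraction``
    valid samples are emitted as all-missing rows (the tree learners
    handle missing values natively). Pass ``values`` to extract features
    from an alternative series on the same grid/mask (e.g. the
    desaturation-free residual of a decomposition).

    Returns a DataFrame with ``infant_id``, ``epoch_index``,
    ``epoch_start_age_h`` and the 66 feature columns.
    """
    espec = espec or EpochSpec()
    fspec = fspec or FilterBankSpec(fs=sig.fs)
    x = sig.values if values is None else np.asarray(values, dtype=float)
    if len(x) != len(sig.values):
        raise ValueError("values must match the signal grid")
    n = len(x)
    ep_len = int(round(espec.epoch_hours * 3600 * sig.fs))
    step = int(round(espec.step_hours * 3600 * sig.fs))
    if n < ep_len:
        raise ValueError("recording shorter than one epoch")
    bands = dyadic_filter_bank(
        UniformSignal(sig.infant_id, sig.channel, sig.fs, x,
                      sig.valid_mask, sig.start_postnatal_age),
        fspec,
    )
    rows = []
    starts = range(0, n - ep_len + 1, step)
    for idx, s in enumerate(starts):
        e = s + ep_len
        start_age = sig.start_postnatal_age + s / sig.fs / 3600.0
        mid_age = start_age + espec.epoch_hours / 2.0
        row = {"infant_id": sig.infant_id, "epoch_index": idx,
               "epoch_start_age_h": start_age}
        frac_valid = sig.valid_mask[s:e].mean()
        if frac_valid < espec.min_valid_fraction:
            row.update({c: np.nan for c in FEATURE_COLUMNS})
            row["postnatal_age_h"] = mid_age
        else:
            for b in range(N_BANDS):
                for stat, val in _band_features(bands[b][s:e], sig.fs).items():
                    row[f"b{b}_{stat}"] = val
            row["postnatal_age_h"] = mid_age
        rows.append(row)
    return pd.DataFrame(rows, columns=["infant_id", "epoch_index",
                                       "epoch_start_age_h"] + FEATURE_COLUMNS)
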