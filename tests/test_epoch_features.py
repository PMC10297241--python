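"""Filter bank, envelope, instantaneous frequency, Higuchi FD and the
66-feature epoch matrix."""

import numpy as np
import pytest
from scipy.stats import kurtosis, skew

from neoprd.epoch_features import (FEATURE_COLUMNS, EpochSpec, FilterBankSpec,
                                   dyadic_filter_bank, envelope,
                                   extract_epoch_features, higuchi_fd,
                                   instantaneous_frequency)

from conftest import make_uniform

FS = 1.0 / 6.0


class TestFilterBank:
    def test_returns_exactly_five_bands(self):
        sig = make_uniform(np.random.default_rng(0).normal(70, 2, 4000))
        bands = dyadic_filter_bank(sig)
        assert len(bands) == 5
        assert all(len(b) == len(sig) for b in bands)

    def test_bandwidths_halve(self):
        spec = FilterBankSpec(fs=FS)
        bw = spec.bandwidths()
        assert len(bw) == 5
        assert bw[0] == pytest.approx(FS / 2)
        for a, b in zip(bw, bw[1:]):
            assert b == pytest.approx(a / 2)

    @pytest.mark.parametrize("mode", ["nested-lowpass", "octave-bandpass"])
    def test_in_band_sinusoid_passes_last_band(self, mode):
        spec = FilterBankSpec(fs=FS, mode=mode)
        f0 = 0.9 * spec.a / 2**4
        n = np.arange(20000)
        x = np.sin(2 * np.pi * f0 * n / FS)
        bands = dyadic_filter_bank(make_uniform(70 + x), spec)
        y = bands[4] - bands[4].mean()
        interior = slice(2000, -2000)
        gain = np.sqrt(np.mean(y[interior] ** 2) / np.mean(x[interior] ** 2))
        assert gain > 0.9

    def test_constant_preserved_in_nested_bands(self):
        bands = dyadic_filter_bank(make_uniform(np.full(4000, 70.0)))
        for b in bands:
            assert np.allclose(b[100:-100], 70.0, atol=1e-6)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            dyadic_filter_bank(make_uniform(np.zeros(100)))


class TestEnvelope:
    def test_constant(self):
        env = envelope(np.full(500, 3.5))
        assert np.allclose(env[10:-10], 3.5, atol=1e-3)

    def test_sinusoid_amplitude(self):
        n = np.arange(2000)
        env = envelope(4.0 * np.sin(2 * np.pi * 0.05 * n))
        assert np.allclose(env[100:-100], 4.0, rtol=0.02)

    def test_am_signal_tracks_modulator(self):
        n = np.arange(4000)
        mod = 1.0 + 0.5 * np.sin(2 * np.pi * 0.002 * n)
        x = mod * np.sin(2 * np.pi * 0.1 * n)
        env = envelope(x)[200:-200]
        target = mod[200:-200]
        rms = np.sqrt(np.mean((env - target) ** 2)) / np.mean(target)
        assert rms < 0.05


class TestInstantaneousFrequency:
    def test_sinusoid_frequency(self):
        t = np.arange(4000) / FS
        x = np.sin(2 * np.pi * 0.02 * t)
        inst = instantaneous_frequency(x, FS)
        assert np.median(inst[100:-100]) == pytest.approx(0.02, rel=0.05)

    def test_linear_chirp(self):
        fs = 1.0
        n = 4000
        t = np.arange(n) / fs
        f0, f1 = 0.05, 0.15
        phase = 2 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2 * t[-1]))
        x = np.sin(phase)
        inst = instantaneous_frequency(x, fs)
        expected = f0 + (f1 - f0) * t / t[-1]
        interior = slice(200, -200)
        rel = np.abs(inst[interior] - expected[interior]) / expected[interior]
        assert np.median(rel) < 0.05

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            instantaneous_frequency(np.full(100, 1.0), FS)


class TestHiguchi:
    def test_straight_line_dimension_one(self):
        assert higuchi_fd(np.arange(2000.0)) == pytest.approx(1.0, abs=0.05)

    def test_white_noise_dimension_two(self):
        x = np.random.default_rng(3).standard_normal(2400)
        assert higuchi_fd(x) == pytest.approx(2.0, abs=0.1)

    def test_range_bounds(self):
        rng = np.random.default_rng(1)
        inputs = [
            np.cumsum(rng.standard_normal(2000)),           # brownian ~1.5
            np.sin(2 * np.pi * 0.01 * np.arange(2000)),
            rng.standard_normal(2000),
        ]
        for x in inputs:
            assert 0.95 <= higuchi_fd(x) <= 2.1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            higuchi_fd(np.arange(50.0), kmax=8)


@pytest.fixture(scope="module")
def noise_signal():
    rng = np.random.default_rng(11)
    return make_uniform(70 + rng.normal(0, 2, int(72 * 3600 * FS)), start_age=6.0)


class TestEpochMatrix:
    def test_exactly_66_columns_and_35_epochs(self, noise_signal):
        df = extract_epoch_features(noise_signal)
        assert len(FEATURE_COLUMNS) == 66
        assert list(df.columns[3:]) == FEATURE_COLUMNS
        # 72-h fully valid recording: floor((72-4)/2)+1 epochs
        assert len(df) == 35

    def test_epoch_step_is_two_hours(self, noise_signal):
        df = extract_epoch_features(noise_signal)
        steps = np.diff(df["epoch_start_age_h"].to_numpy())
        assert np.allclose(steps, 2.0)
        assert df["postnatal_age_h"].iloc[0] == pytest.approx(6.0 + 2.0)

    def test_white_noise_band0_moments(self, noise_signal):
        df = extract_epoch_features(noise_signal)
        x = noise_signal.values[: int(4 * 3600 * FS)]
        assert df["b0_skew"].iloc[0] == pytest.approx(skew(x), abs=1e-9)
        assert df["b0_skew"].iloc[0] == pytest.approx(0.0, abs=0.2)
        assert df["b0_kurt"].iloc[0] == pytest.approx(kurtosis(x, fisher=False), abs=1e-9)
        assert df["b0_kurt"].iloc[0] == pytest.approx(3.0, abs=0.5)

    def test_low_valid_epoch_emits_missing_row(self):
        rng = np.random.default_rng(0)
        n = int(8 * 3600 * FS)
        valid = np.ones(n, dtype=bool)
        valid[: int(2.0 * 3600 * FS)] = False  # first epoch 50 % valid
        sig = make_uniform(70 + rng.normal(0, 1, n), valid=valid)
        df = extract_epoch_features(sig)
        assert df.loc[0, "b0_env_mean"] != df.loc[0, "b0_env_mean"]  # NaN
        assert np.isfinite(df.loc[1, "b0_env_mean"])
        assert np.isfinite(df.loc[0, "postnatal_age_h"])

    def test_amplitude_equivariance(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1.0, int(4 * 3600 * FS))
        a = extract_epoch_features(make_uniform(base))
        b = extract_epoch_features(make_uniform(3.0 * base))
        for col in ("b0_env_sd", "b1_env_sd"):
            assert b[col].iloc[0] == pytest.approx(3.0 * a[col].iloc[0], rel=1e-6)
        for col in ("b0_if_mean", "b0_fd", "b2_if_sd", "b3_fd"):
            assert b[col].iloc[0] == pytest.approx(a[col].iloc[0], abs=1e-6)

    def test_short_recording_rejected(self):
        sig = make_uniform(np.zeros(100))
        with pytest.raises(ValueError, match="shorter than one epoch"):
            extract_epoch_features(sig)
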