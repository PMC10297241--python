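"""SSA decomposition, PRD component extraction and event segmentation."""

import numpy as np
import pytest

from neoprd.prd import (SSAConfig, extract_prd_component, segment_events,
                        ssa_decompose)
from neoprd.preprocess import preprocess_channel
from neoprd.synthetic import PRDSpec, RecordingSpec, generate_recording

from conftest import make_uniform

FS = 1.0 / 6.0


class TestSSA:
    CFG = SSAConfig(window_length=30)

    def test_constant_concentrates_in_first_component(self):
        x = np.full(200, 3.0)
        comps = ssa_decompose(x, self.CFG)
        assert np.allclose(comps[0], 3.0, atol=1e-8)
        assert np.abs(comps[1:]).max() < 1e-8

    def test_sinusoid_needs_two_components(self):
        n = np.arange(400)
        x = np.sin(2 * np.pi * 0.05 * n)
        comps = ssa_decompose(x, self.CFG)
        energy = (comps**2).sum(axis=1)
        assert energy[:2].sum() / energy.sum() > 0.99

    def test_reconstruction_identity_white_noise(self):
        x = np.random.default_rng(0).standard_normal(500)
        comps = ssa_decompose(x, self.CFG)
        assert np.abs(comps.sum(axis=0) - x).max() < 1e-8

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="smaller window"):
            ssa_decompose(np.zeros(50), self.CFG)


@pytest.fixture(scope="module")
def one_dip_decomposition():
    """24-h artifact-free recording with a single known 8-min dip."""
    spec = RecordingSpec(duration=24.0, prd_rate=0.0, dropout_rate=0.0,
                         floor_rate=0.0, seed=5)
    ev = PRDSpec(onset_time=10 * 3600.0, duration=480.0, nadir_depth=12.0)
    raw, _ = generate_recording(spec, events=[ev])
    sig = preprocess_channel(raw)
    dec = extract_prd_component(sig)
    return ev, sig, dec


class TestExtraction:
    def test_no_transient_signal_gives_quiet_component(self):
        spec = RecordingSpec(duration=12.0, prd_rate=0.0, noise_sd=0.0,
                             dropout_rate=0.0, floor_rate=0.0, seed=2)
        raw, _ = generate_recording(spec)
        sig = preprocess_channel(raw)
        dec = extract_prd_component(sig)
        rms = np.sqrt(np.mean(dec.prd_component[sig.valid_mask] ** 2))
        assert rms < 0.5

    def test_injected_dip_lands_in_component(self, one_dip_decomposition):
        ev, sig, dec = one_dip_decomposition
        t = sig.times
        win = (t >= ev.onset_time) & (t <= ev.onset_time + ev.duration)
        from neoprd.synthetic import prd_waveform
        injected = prd_waveform(t, ev)
        captured = -dec.prd_component[win]
        # at least 70 % of the injected event energy is in the component
        e_inj = (injected[win] ** 2).sum()
        e_cap = (np.clip(captured, 0, None) * injected[win]).sum()
        assert e_cap / e_inj > 0.7
        # and the residual no longer dips deeply
        base = np.median(dec.residual[win])
        assert base - dec.residual[win].min() < 3.0

    def test_additive_identity(self, one_dip_decomposition):
        _, sig, dec = one_dip_decomposition
        err = np.abs(dec.prd_component + dec.residual - sig.values)
        assert err.max() < 1e-6

    def test_short_segment_skipped_with_warning(self, caplog):
        import logging
        sig = make_uniform(70.0 + np.random.default_rng(0).normal(0, 1, 600))
        with caplog.at_level(logging.WARNING):
            dec = extract_prd_component(sig)
        assert np.all(dec.prd_component == 0)
        assert any("too short" in r.message for r in caplog.records)


class TestSegmentation:
    def test_zero_component_yields_no_events(self):
        sig = make_uniform(np.full(2400, 70.0))
        from neoprd.prd import PRDDecomposition
        dec = PRDDecomposition(sig, np.zeros(2400), sig.values.copy())
        assert segment_events(dec) == []

    def test_single_dip_event_timing(self, one_dip_decomposition):
        ev, sig, dec = one_dip_decomposition
        events = segment_events(dec)
        near = [e for e in events
                if ev.onset_time - 120 <= e.nadir_time <= ev.onset_time + ev.duration + 120]
        assert len(near) == 1
        got = near[0]
        assert abs(got.nadir_time - ev.nadir_time) <= 30.0
        assert abs(got.duration - ev.duration) <= 0.2 * ev.duration
        assert got.onset_time < got.nadir_time < got.offset_time
        assert got.nadir_amplitude == pytest.approx(12.0, abs=3.0)
        assert got.slope_down < 0 < got.slope_up

    def test_two_dips_interval(self):
        spec = RecordingSpec(duration=24.0, prd_rate=0.0, dropout_rate=0.0,
                             floor_rate=0.0, seed=8)
        evs = [
            PRDSpec(onset_time=8 * 3600.0, duration=360.0, nadir_depth=12.0),
            PRDSpec(onset_time=8 * 3600.0 + 1800.0 - 120.0 + 360.0, duration=360.0,
                    nadir_depth=12.0),
        ]
        # nadirs 30 min apart: nadir = onset + duration/3 for asymmetry 0.5
        evs[1].onset_time = evs[0].nadir_time + 1800.0 - evs[1].duration / 3.0
        raw, _ = generate_recording(spec, events=evs)
        dec = extract_prd_component(preprocess_channel(raw))
        events = segment_events(dec)
        assert len(events) == 2
        gap = events[1].nadir_time - events[0].nadir_time
        assert gap == pytest.approx(1800.0, abs=60.0)


def test_recovered_depth_monotone_in_injected_depth():
    """Deeper injections never recover shallower, at a fixed noise seed."""
    recovered = []
    for depth in (6.0, 8.0, 10.0, 12.0, 14.0):
        spec = RecordingSpec(duration=24.0, prd_rate=0.0, dropout_rate=0.0,
                             floor_rate=0.0, seed=13)
        ev = PRDSpec(onset_time=12 * 3600.0, duration=480.0, nadir_depth=depth)
        raw, _ = generate_recording(spec, events=[ev])
        dec = extract_prd_component(preprocess_channel(raw))
        events = segment_events(dec)
        hits = [e for e in events
                if e.onset_time <= ev.nadir_time <= e.offset_time]
        recovered.append(hits[0].nadir_amplitude if hits else 0.0)
    assert all(b >= a - 1e-9 for a, b in zip(recovered, recovered[1:]))
    assert recovered[-1] > 10.0


def test_false_positive_control_on_event_free_recordings():
    """Median detected event count over event-free recordings is zero."""
    counts = []
    for seed in range(20):
        spec = RecordingSpec(duration=12.0, prd_rate=0.0, dropout_rate=0.0,
                             floor_rate=0.0, seed=300 + seed)
        raw, _ = generate_recording(spec)
        dec = extract_prd_component(preprocess_channel(raw))
        counts.append(len(segment_events(dec)))
    assert np.median(counts) == 0
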