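"""Shared fixtures: small synthetic signals built once per session."""

import numpy as np
import pytest

from neoprd.preprocess import UniformSignal
from neoprd.synthetic import PRDSpec, RecordingSpec, generate_recording

FS = 1.0 / 6.0


def make_uniform(values, infant_id="t01", channel="rcSO2", fs=FS, valid=None,
                 start_age=0.0):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(len(values), dtype=bool)
    return UniformSignal(infant_id=infant_id, channel=channel, fs=fs,
                         values=values, valid_mask=valid,
                         start_postnatal_age=start_age)


@pytest.fixture(scope="session")
def clean_spec():
    """A 24-h artifact-free recording spec (no dropouts/floor episodes)."""
    return RecordingSpec(duration=24.0, dropout_rate=0.0, floor_rate=0.0, seed=42)


@pytest.fixture(scope="session")
def quiet_spec():
    """A 24-h recording with no events, noise or drift."""
    return RecordingSpec(duration=24.0, prd_rate=0.0, noise_sd=0.0,
                         drift_amplitude=0.0, dropout_rate=0.0, floor_rate=0.0,
                         baseline_level=70.0, seed=7)


@pytest.fixture(scope="session")
def recorded_with_truth(clean_spec):
    raw, truth = generate_recording(clean_spec)
    raw.infant_id = "t01"
    return raw, truth
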