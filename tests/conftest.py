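import numpy as np
import pytest

from entropath import CohortConfig, EegRecording, preprocess


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A cohort config sized for fast tests (short recordings, few regions)."""
    return CohortConfig(recording_duration=30.0, n_regions=60, n_modules=4, seed=0)


def make_recording(data, fs=300.0, channels=None):
    """Wrap a raw array as an EegRecording with dummy provenance."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return EegRecording(
        subject="sub-00", dose="1mg", timepoint="baseline",
        channels=channels, sampling_rate=fs, data=data,
    )


@pytest.fixture
def sinusoid_epochs():
    """Band-passed, epoched 10 Hz sinusoid: 30 s, one channel, 300 Hz."""
    t = np.arange(9000) / 300.0
    rec = make_recording(np.sin(2 * np.pi * 10.0 * t))
    return preprocess(rec)
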