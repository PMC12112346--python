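import numpy as np
import pytest

from retinaosc.io import Band, Recording, StimulusEvent, TraceView


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_trace():
    """Factory for single-frequency test traces."""

    def make(freq_hz, fs=10_000.0, duration_s=10.0, amp=1.0, band=Band.RAW):
        t = np.arange(int(duration_s * fs)) / fs
        return TraceView(amp * np.sin(2 * np.pi * freq_hz * t), fs, 0.0, "ch0", band)

    return make


@pytest.fixture
def small_recording(rng):
    """10-s, 3-channel noise recording with two stimulus events."""
    fs = 1000.0
    traces = rng.normal(0.0, 10.0, size=(10_000, 3))
    return Recording(
        traces=traces,
        fs=fs,
        channel_ids=["e1", "e2", "e3"],
        stim_events=[StimulusEvent(time=2.0), StimulusEvent(time=4.999)],
    )
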