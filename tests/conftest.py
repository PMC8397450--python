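import numpy as np
import pytest

from betalock.core_io import (
    ChannelMeta,
    Episode,
    ForelimbCodeSeries,
    LfpRecording,
    RotationRateSeries,
    SessionBundle,
    SessionConfig,
    StateIntervals,
    TrackingTrace,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(samples, sample_rate=1100.0, group="sham", subject="SH01"):
    """Single-channel recording with valid metadata for quick spectral tests."""
    samples = np.atleast_2d(samples)
    chans = [
        ChannelMeta("M1", "left", False, subject, group) for _ in range(samples.shape[0])
    ]
    return LfpRecording(samples, sample_rate, chans)


@pytest.fixture
def tone_recording():
    """10 s of a 20 Hz unit-amplitude tone at 1100 Hz."""
    fs = 1100.0
    t = np.arange(int(10 * fs)) / fs
    return make_recording(np.sin(2 * np.pi * 20.0 * t), fs)


@pytest.fixture
def small_bundle(rng):
    """A tiny but complete cylinder session bundle (8 s)."""
    fs = 1100.0
    dur = 8.0
    n = int(dur * fs)
    chans = [
        ChannelMeta("M1", "left", False, "PD01", "PD"),
        ChannelMeta("M1", "right", True, "PD01", "PD"),
    ]
    lfp = LfpRecording(rng.standard_normal((2, n)), fs, chans)
    codes = ForelimbCodeSeries(rng.integers(0, 16, int(dur / 0.25)), dt=0.25)
    rot = RotationRateSeries(rng.normal(0, 5, int(dur / 0.25)), dt=0.25)
    track = TrackingTrace(
        np.clip(37 + np.cumsum(rng.normal(0, 0.05, int(dur * 25))), 0, 74),
        np.clip(37 + np.cumsum(rng.normal(0, 0.05, int(dur * 25))), 0, 74),
        fps=25.0,
    )
    states = StateIntervals([(0.0, 3.0, "rearing"), (3.0, dur, "inactive")])
    config = SessionConfig(
        paradigm="cylinder",
        episodes=[Episode(0.0, 4.0, False), Episode(4.0, dur, True)],
        group="PD",
        subject_id="PD01",
        assignment="PD-DBS ON",
    )
    return SessionBundle(
        config=config, lfp=lfp, tracking=track, codes=codes, rotation=rot, states=states
    )
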