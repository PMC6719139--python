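import numpy as np
import pytest

from vcgbeat.signal_io import RawRecording, stream_buffers
from vcgbeat.synthetic import SimConfig, synthesize_recording


@pytest.fixture(scope="session")
def default_sim():
    """60 s at the default 70 bpm / 15 dB operating point, seed 42."""
    cfg = SimConfig(seed=42)
    rec, gt = synthesize_recording(cfg)
    return cfg, rec, gt


@pytest.fixture()
def jittered_sine_segment():
    """One 10 s buffer of a 1 Hz sine sampled on a jittered ~250 Hz grid."""
    rng = np.random.default_rng(0)
    n = 2551
    t = np.arange(n) / 250.0 + np.clip(rng.normal(0, 5e-4, n), -0.0018, 0.0018)
    rec = RawRecording(t, {"aZ": np.sin(2 * np.pi * t)}, {"fs": 250.0})
    return next(stream_buffers(rec, 10.0, 1.0))
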