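import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def selfbuilt_recording():
    """Small noise-free 3-class recording, 12 channels at 25 Hz."""
    from harnet.synthetic_data import default_profiles, generate_recording, selfbuilt_channel_meta

    meta = selfbuilt_channel_meta()
    profiles = default_profiles(len(meta), 3)
    for p in profiles:
        p.noise_sd = 0.0
        p.phase_jitter = 0.0
    return generate_recording(profiles, rate_hz=25.0, seconds_per_class=8.0,
                              seed=7, channel_meta=meta)
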