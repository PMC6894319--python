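import numpy as np
import pytest

from hectpipe.synthetic import TwitchSimParams, generate_twitch_trace
from hectpipe.twitch import TwitchConfig


@pytest.fixture(scope="session")
def clean_paced_sim():
    """Noise-free 0.5 Hz paced recording: 15 identical twitches."""
    params = TwitchSimParams(
        mode="paced",
        pace_freq=0.5,
        amplitude_mean=10.0,
        amplitude_cv=0.0,
        noise_sd=0.0,
        baseline_force=20.0,
        duration=30.0,
        sampling_rate=1000.0,
        seed=0,
    )
    return generate_twitch_trace(params)


@pytest.fixture(scope="session")
def fine_cfg():
    """Short-window analysis configuration for finely sampled clean traces."""
    return TwitchConfig(smooth_window_s=0.0015, sg_deriv_window_s=0.0015)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
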