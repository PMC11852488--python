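import numpy as np
import pytest

from emosafe import (
    DEFAULT_PROFILES,
    STATES,
    EmotionProfile,
    generate_recording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_recordings():
    """One 24 s recording per shipped emotion profile (fast fixture)."""
    return [
        generate_recording(DEFAULT_PROFILES[state], duration=24, fs=128, seed=10 + i)
        for i, state in enumerate(STATES)
    ]


@pytest.fixture(scope="session")
def delta_dominant_profile():
    return EmotionProfile(
        "neutral",
        {"delta": 5.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0, "gamma": 1.0},
        complexity=0.1,
    )
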