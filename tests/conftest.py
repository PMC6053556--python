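import numpy as np
import pytest

from matuku import CampaignSpec, DetectionSpec, simulate_campaign


@pytest.fixture
def noiseless_detection():
    """Perfect detection on every channel, no bearing or volume noise."""
    return DetectionSpec(
        p_detect={"OBS": 1.0, "MONO": 1.0, "STEREO": 1.0},
        bearing_noise_sd=0.0,
        volume_misclass_p=0.0,
    )


@pytest.fixture
def default_campaign():
    return simulate_campaign(CampaignSpec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
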