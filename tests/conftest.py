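import numpy as np
import pytest

from rppgnet.network import NetworkConfig
from rppgnet.synthetic import SceneConfig, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# Tiny network used wherever the test only needs a structurally complete model.
TINY_NET = NetworkConfig(
    clip_len=8,
    in_size=(12, 12),
    stem_channels=4,
    block_channels=(6,),
    cbam_reduction=2,
    spatial_kernel=3,
)


@pytest.fixture
def tiny_net_config():
    return TINY_NET


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free, drift-free, jitter-free scene: pure pulse modulation."""
    cfg = SceneConfig(duration_s=6.0, hr_trajectory=72.0, noise_sd=0.0,
                      illumination_drift_amp=0.0, landmark_jitter_sd=0.0, seed=7)
    return render_scene(cfg)


@pytest.fixture(scope="session")
def default_scene():
    """Scene at the generator's default noise/drift/jitter settings."""
    return render_scene(SceneConfig(duration_s=20.0, hr_trajectory=72.0, seed=11))
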