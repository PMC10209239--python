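import numpy as np
import pytest

from facenav.geometry import random_transform
from facenav.synthetic import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_transforms(rng):
    """A batch of seeded random rigid transforms for property tests."""
    return [random_transform(rng) for _ in range(50)]


@pytest.fixture
def noiseless_cfg():
    return ScenarioConfig(seed=7, pixel_noise_px=0.0,
                          tracker_noise_mm=0.0, tracker_noise_deg=0.0,
                          camera_pose_noise_mm=0.0, camera_pose_noise_deg=0.0)
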