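import numpy as np
import pytest
from hypothesis import settings

from fruitfusion.camera import CameraIntrinsics
from fruitfusion.synth import SceneParams, generate_scene

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def intr():
    """Small pinhole camera for fast geometric tests."""
    return CameraIntrinsics(fx=100.0, fy=100.0, cx=20.0, cy=15.0,
                            mw=40, mh=30)


@pytest.fixture(scope="session")
def scene():
    """One deterministic synthetic orchard scene at default settings."""
    return generate_scene(SceneParams(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
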