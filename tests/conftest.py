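import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from armfuse.arm_model import default_arm_chain
from armfuse.synthetic import CameraModel, MotionScript, NoiseModel, generate_trajectory, synthesize_imu

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def chain():
    return default_arm_chain()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def efe_truth(chain):
    """Full-protocol elbow flexion/extension trajectory (7 slow + 2 fast)."""
    return generate_trajectory(MotionScript("EFE"), chain)


@pytest.fixture(scope="session")
def efe_clean_stream(efe_truth):
    """Noise-free streams incl. the camera channel for the EFE trajectory."""
    return synthesize_imu(efe_truth, noise=NoiseModel.zero(), camera=CameraModel())


@pytest.fixture(scope="session")
def short_efe_truth(chain):
    """Scaled-down EFE (2 slow + 1 fast cycles) for faster filter tests."""
    return generate_trajectory(MotionScript("EFE", slow_cycles=2, fast_cycles=1), chain)


@pytest.fixture(scope="session")
def short_efe_clean(short_efe_truth):
    return synthesize_imu(short_efe_truth, noise=NoiseModel.zero(), camera=CameraModel())
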