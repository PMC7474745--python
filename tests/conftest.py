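import numpy as np
import pytest

from shoulder_torque import synthetic_data as sd
from shoulder_torque.robot_model import default_robot


@pytest.fixture(scope="session")
def robot():
    return default_robot()


@pytest.fixture(scope="session")
def scene(robot):
    return sd.default_scene(robot)


@pytest.fixture(scope="session")
def field():
    return sd.default_field()


@pytest.fixture(scope="session")
def orthosis():
    return sd.default_orthosis()


@pytest.fixture(scope="session")
def short_trajectory():
    return sd.generate_trajectory(sd.TrajectorySpec(n_samples=40, seed=7))


@pytest.fixture(scope="session")
def flange_scene(short_trajectory, field, scene, orthosis):
    """Noiseless flange-level log + ground truth on a short run."""
    return sd.render_flange_log(short_trajectory, field, scene, orthosis, noise_sigma=0.0)


@pytest.fixture(scope="session")
def robot_scene(field, scene, orthosis):
    """Noiseless robot-level log + ground truth on a short run."""
    traj = sd.generate_trajectory(sd.TrajectorySpec(n_samples=30, seed=3))
    return sd.render_robot_log(traj, field, scene, orthosis, noise_sigma=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
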