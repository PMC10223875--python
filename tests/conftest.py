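import numpy as np
import pytest

from tofusion.camera import Pose
from tofusion.synthetic import (
    default_phantom,
    default_rig,
    make_target_pose,
    render_calibration_scene,
    render_phantom_scene,
)
from tofusion.targets import GridSpec


@pytest.fixture(scope="session")
def rig():
    return default_rig()


@pytest.fixture(scope="session")
def grid_spec():
    return GridSpec()


@pytest.fixture(scope="session")
def target_pose(grid_spec):
    return make_target_pose(grid_spec, distance=0.45, rvec=(0.04, -0.03, 0.02))


@pytest.fixture(scope="session")
def calib_scene(rig, grid_spec, target_pose):
    """One noise-free rendered calibration scene, shared across tests."""
    return render_calibration_scene(rig, grid_spec, target_pose, seed=11)


@pytest.fixture(scope="session")
def phantom_scene(rig):
    """One noise-free phantom scene at 0.45 m on the ToF axis."""
    pose = Pose(np.zeros(3), np.array([0.0, 0.0, 0.45]))
    return render_phantom_scene(rig, default_phantom(), pose, seed=5)
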