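import numpy as np
import pytest

from mlgait import cameras as cm
from mlgait import synthetic_gait as sg


@pytest.fixture(scope="session")
def rig():
    return sg.default_camera_rig()


@pytest.fixture(scope="session")
def camera_map(rig):
    return {c.camera_id: c for c in rig}


@pytest.fixture(scope="session")
def default_walk():
    """Noise-free walk at the default (realism) configuration."""
    config = sg.GaitSimConfig(duration_s=6.0)
    return sg.simulate_walk(config)


@pytest.fixture(scope="session")
def identity_camera():
    K = np.array([[100.0, 0.0, 50.0], [0.0, 100.0, 50.0], [0.0, 0.0, 1.0]])
    return cm.CameraModel("ident", K, np.eye(3), np.zeros(3), image_size=(100, 100))


def random_camera(rng, with_distortion=True):
    """A camera at a random position looking at a point near the origin."""
    from scipy.spatial.transform import Rotation

    pos = rng.uniform(-1, 1, 3) * np.array([2.0, 0.5, 2.0]) + np.array([0, 1.2, 4.0])
    target = rng.uniform(-0.3, 0.3, 3)
    z = target - pos
    z /= np.linalg.norm(z)
    up = np.array([0.0, 1.0, 0.0])
    x = np.cross(z, up)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    t = -R @ pos
    f = rng.uniform(800, 1400)
    K = np.array([[f, 0.0, 646.0], [0.0, f, 482.0], [0.0, 0.0, 1.0]])
    dist = (np.array([rng.uniform(-0.1, 0.1), rng.uniform(-0.02, 0.02),
                      rng.uniform(-0.003, 0.003), rng.uniform(-0.003, 0.003)])
            if with_distortion else np.zeros(4))
    return cm.CameraModel(f"rc{rng.integers(1 << 30)}", K, R, t, distortion=dist)
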