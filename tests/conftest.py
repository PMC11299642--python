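import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def hexagon():
    """Planar regular hexagon of aromatic-like C-C distance 1.40 A."""
    from radscav.simulate import regular_polygon_geometry

    return regular_polygon_geometry(6, 1.4)


@pytest.fixture()
def random_rotation():
    """A fixed but non-trivial proper rotation matrix."""
    rng = np.random.default_rng(12345)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def rotation_about_x(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    return np.array([
        [1.0, 0.0, 0.0],
        [0.0, math.cos(a), -math.sin(a)],
        [0.0, math.sin(a), math.cos(a)],
    ])
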