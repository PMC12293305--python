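import math

import numpy as np
import pytest

from canine_trace.geometry_core import RigidTransform
from canine_trace.synthetic_data import SceneSpec, make_case


def random_rigid(rng: np.random.Generator, max_angle_deg: float = 180.0,
                 max_shift: float = 25.0) -> RigidTransform:
    """Uniform-ish random proper rigid motion for property tests."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(0.0, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)
    return RigidTransform(R, rng.uniform(-max_shift, max_shift, 3))


@pytest.fixture(scope="session")
def noiseless_case():
    """One noiseless synthetic case shared by read-only tests."""
    return make_case(SceneSpec(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
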