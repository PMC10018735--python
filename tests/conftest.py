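import numpy as np
import pytest

from lincsopt import (Configuration, make_alkane, make_coupled_triangles,
                      make_hinge_cholesterol_like, make_trapezoid)
from lincsopt.equimomental import RigidBodySpec

MINIMAL_ITP = """\
[ moleculetype ]
DIM 1

[ atoms ]
  1 P1 1 DIM A1 1 0.0 72.0
  2 P1 1 DIM A2 2 0.0 72.0

[ constraints ]
  1 2 1 0.47
"""


@pytest.fixture
def minimal_itp():
    return MINIMAL_ITP


@pytest.fixture
def equilateral():
    return make_coupled_triangles(side=0.3, masses=(72.0,) * 4)


@pytest.fixture
def hinge():
    return make_hinge_cholesterol_like()


@pytest.fixture
def butane():
    return make_alkane(4)


@pytest.fixture
def pentane():
    return make_alkane(5)


@pytest.fixture
def trapezoid():
    return make_trapezoid()


@pytest.fixture
def random_cloud():
    rng = np.random.default_rng(42)
    return RigidBodySpec(positions=rng.normal(size=(5, 3)),
                         masses=rng.uniform(1.0, 100.0, size=5))


def all_fixture_pairs():
    """Every generated (topology, configuration) pair, for sweep tests."""
    return [
        ("equilateral", make_coupled_triangles()),
        ("skewed_triangles", make_coupled_triangles(
            positions=np.array([[0.0, 0.336, 0.0], [0.08, 0.0, 0.0],
                                [0.4888, 0.16, 0.032], [0.832, -0.192, 0.0]]),
            masses=(72.0, 36.0, 36.0, 159.0))),
        ("butane", make_alkane(4)),
        ("butane_bonds_only", make_alkane(4, constrain_angles=False)),
        ("pentane", make_alkane(5)),
        ("trapezoid_long", make_trapezoid(diagonal="long")),
        ("trapezoid_short", make_trapezoid(diagonal="short")),
        ("hinge", make_hinge_cholesterol_like()),
    ]


def rigid_motion(config: Configuration, seed: int = 0) -> Configuration:
    """A random proper rotation plus translation of a snapshot."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return config.transformed(rotation=q, translation=rng.normal(size=3))
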