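import numpy as np
import pytest

from octmatch.geometry import TargetPolygon


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def triangle():
    """A scalene target triangle with ~10 Å edges."""
    return TargetPolygon(np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [5.0, 8.0, 0.0]]))


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a bounded translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    trans = rng.uniform(-20, 20, size=3)
    return rot, trans
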