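import numpy as np
import pytest

from isopepgraft.fixtures import (
    make_graft_fixture_pair,
    make_isopeptide_fixture,
)


@pytest.fixture(scope="session")
def planted_structure():
    """Default isopeptide fixture: cis bond at 1.33 Å with a 2-conformer Glu."""
    structure, truth = make_isopeptide_fixture(seed=0)
    return structure, truth


@pytest.fixture(scope="session")
def graft_pair():
    """Template/target pair whose correct design is N13K/Q67E/P117N + V26F."""
    return make_graft_fixture_pair(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rigid_transform(rng):
    """A random proper rotation (via normalized quaternion) and translation."""
    q = rng.normal(size=4)
    w, x, y, z = q / np.linalg.norm(q)
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-50, 50, 3)
    return R, t
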