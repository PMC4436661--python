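import numpy as np
import pytest

from rnassess import build_helix

#: ~2000-atom duplex used by the noise-recovery checks (96 nt).
LONG_SEQ = "GCAUGGCUAAUCACCAUGAUGCAAUCGGGUUGAACACUUAAUUGGGUU"


@pytest.fixture(scope="session")
def duplex6():
    return build_helix("GCAUGC", label="duplex6")


@pytest.fixture(scope="session")
def duplex12():
    return build_helix("GCAUGCAUGCAU", label="duplex12")


@pytest.fixture(scope="session")
def duplex_large():
    return build_helix(LONG_SEQ, label="duplex-large")


def random_rigid_motion(rng):
    """A uniform-ish proper rotation plus a translation, seeded."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, 2 * np.pi)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    t = rng.uniform(-20, 20, size=3)
    return R, t
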