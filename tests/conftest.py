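import math

import numpy as np
import pytest

from waxcomb.config import derive_kinematics, validate_config
from waxcomb.grid import WaxGrid


@pytest.fixture(scope="session")
def default_cfg():
    """Canonical parameter set (unit square, 100x100 lattice)."""
    return validate_config({})


@pytest.fixture(scope="session")
def default_kin(default_cfg):
    return derive_kinematics(default_cfg)


@pytest.fixture()
def empty_grid(default_cfg, default_kin):
    occ = np.zeros((default_cfg.N_y, default_cfg.N_x), dtype=bool)
    return WaxGrid(occ, default_kin.dx, default_kin.dy)


def make_grid(cells, n=100, dx=0.01):
    """Small helper: grid with the given (i, j) cells switched on."""
    occ = np.zeros((n, n), dtype=bool)
    for i, j in cells:
        occ[j, i] = True
    return WaxGrid(occ, dx, dx)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
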