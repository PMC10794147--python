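import math

import numpy as np
import pytest

import multinuc as mn


@pytest.fixture(scope="session")
def mini_unique():
    """Fully unique design of the three 5x5 letter masks (42 tiles)."""
    return mn.make_fixture_system(seed=1, merged=False)


@pytest.fixture(scope="session")
def mini_merged():
    """Merged mini three-letter system (deterministic, seed 1)."""
    return mn.make_fixture_system(seed=1, merged=True)


@pytest.fixture(scope="session")
def block3():
    """Three-shape shared-block fixture (10x10 blocks, seed 1)."""
    return mn.make_shared_block_fixture(seed=1)


@pytest.fixture
def params():
    """G_se = 3 RT, alpha = 0, u0 = 1 M: the uniform worked-example regime."""
    return mn.EnergyParams(g_se=3.0)


def uniform_gmc_pattern(tile_names, g_mc: float) -> mn.ConcentrationPattern:
    """Concentrations such that every tile has chemical potential g_mc RT."""
    c_nm = math.exp(-g_mc) * 1e9
    return mn.ConcentrationPattern.uniform(tile_names, c_nm)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
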