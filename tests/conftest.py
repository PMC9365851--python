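import logging
import warnings

import numpy as np
import pytest

import hurpgap as hg

logging.getLogger("hurpgap").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def truth():
    """Ground-truth parameter fixture for synthetic experiments."""
    return hg.default_true_params()


@pytest.fixture(scope="session")
def coarse_grid():
    """Fast solver grid for tests that do not probe spatial accuracy."""
    return hg.SpatialGrid(L=3.0, n_cells=60)


@pytest.fixture(scope="session")
def default_grid():
    return hg.default_grid()


@pytest.fixture(scope="session")
def gap_base(truth):
    """Parameter set at which the trailing steady state shows a clear
    half-maximum gap (stronger kinetochore absorption, flatter RanGTP
    gradient than the synthetic fixture)."""
    return truth.replace(gamma1=0.1, s=6.0)


@pytest.fixture(scope="session")
def small_dataset(truth):
    """One noisy synthetic profile dataset on a coarse generation grid."""
    return hg.generate_profile_dataset(
        truth, seed=7, grid=hg.SpatialGrid(L=3.0, n_cells=90))
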