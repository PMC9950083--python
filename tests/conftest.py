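import numpy as np
import pytest

from domescatter.refindex import default_chemistry, default_grid, synthesize
from domescatter.subspace import TrainingGrid, build_training_set, fit_subspace


@pytest.fixture(scope="session")
def chem():
    return default_chemistry()


@pytest.fixture(scope="session")
def grid():
    """Default analysis grid, 1000-6000 cm^-1 step 2."""
    return default_grid()


@pytest.fixture(scope="session")
def coarse_grid():
    """Coarser grid for quadrature-oracle comparisons."""
    return default_grid(1000, 6000, 10.0)


@pytest.fixture(scope="session")
def index_spectrum(chem, grid):
    return synthesize(chem, grid)


@pytest.fixture(scope="session")
def sphere_basis(chem, grid):
    """PCA basis of the default 100-curve sphere training set."""
    curves = build_training_set(chem, TrainingGrid.default(), grid)
    return fit_subspace(curves, 20)


@pytest.fixture(scope="session")
def training_curves(chem, grid):
    return build_training_set(chem, TrainingGrid.default(), grid)
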