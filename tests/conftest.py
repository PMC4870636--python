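import numpy as np
import pandas as pd
import pytest

from carmap.lattice import LatticeSpec, make_grid_adjacency
from carmap.synthetic import simulate_dataset


@pytest.fixture(scope="session")
def grid56():
    """7x8 rook lattice, the default stand-in for the 53-area catchment."""
    return make_grid_adjacency(LatticeSpec(7, 8, "rook"))


@pytest.fixture(scope="session")
def grid12():
    """Small 3x4 lattice for MCMC-heavy checks."""
    return make_grid_adjacency(LatticeSpec(3, 4, "rook"))


@pytest.fixture(scope="session")
def dataset56():
    """One synthetic catchment at the default generative conditions."""
    return simulate_dataset(seed=42)


@pytest.fixture(scope="session")
def design56(dataset56):
    """Intercept + ECON design, offset, for the default dataset."""
    n = dataset56.n_areas
    X = pd.DataFrame(
        {"intercept": np.ones(n), "ECON": dataset56.covariates["ECON"].to_numpy()}
    )
    return X, dataset56.offset
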