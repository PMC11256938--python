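import numpy as np
import pytest

from scvic import TrainingConfig, fit
from scvic.simulation import SimulationScenario, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """Three well-separated groups, 300 cells x ~200 genes."""
    return simulate(
        SimulationScenario(n_groups=3, n_cells=300, n_genes=200, de_fac_loc=0.8, seed=0)
    )


@pytest.fixture(scope="session")
def fitted_state(small_dataset):
    """A briefly trained mixture model shared across read-only tests."""
    cfg = TrainingConfig(
        n_components=3, max_epochs=100, seed=0, convergence_tol=0.0
    )
    return fit(small_dataset, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
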