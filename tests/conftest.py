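import numpy as np
import pytest

from scmodules.io import make_data_splits
from scmodules.simulate import SimulationConfig, simulate_bundle
from scmodules.workflow import _stage_seeds, fit_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A quick strong-signal scenario: 3 modules x 15 genes, 12 regulators."""
    cfg = SimulationConfig(
        n_cells=400,
        n_regulators=12,
        n_modules=3,
        genes_per_module=15,
        regulators_per_module=2,
        seed=5,
    )
    bundle, truth = simulate_bundle(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """One converged fit on the small scenario, shared across tests."""
    cfg, bundle, truth = small_sim
    split_seed, grid_seed = _stage_seeds(5, 2)
    splits = make_data_splits(bundle, seed=split_seed)
    fits = fit_grid(splits, [3], [0.1], seed=grid_seed)
    return splits, fits[(3, 0.1)], truth
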