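import numpy as np
import pytest

from ecoconverge.synth import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """One shared small simulated dataset (deterministic)."""
    return simulate_dataset(SimConfig(seed=11, n_genes=200))


@pytest.fixture(scope="session")
def toy_tree_newick():
    return "((A:1,B:1):2,C:3);"


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
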