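import numpy as np
import pytest

from cgrmap.phylo import random_coalescent_tree, read_newick
from cgrmap.simulate import PangenomeSimConfig, simulate_pangenome

SMALL_NEWICK = "((A:0.3,B:0.5):0.2,((C:0.4,D:0.1):0.3,(E:0.2,F:0.6):0.1):0.4);"


@pytest.fixture(scope="session")
def small_tree():
    return read_newick(SMALL_NEWICK, from_string=True)


@pytest.fixture(scope="session")
def tree24():
    """Fixed 24-tip coalescent tree used for K calibration."""
    return random_coalescent_tree(24, seed=42)


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated strain collection shared across tests."""
    cfg = PangenomeSimConfig(n_genomes=10, n_core=20, n_accessory=20,
                             planted_cluster_size=4, fraction_metabolizers=0.4,
                             per_site_divergence=0.01, seed=11)
    return simulate_pangenome(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
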