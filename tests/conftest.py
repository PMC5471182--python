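import numpy as np
import pytest

from crypsis.phylo_eigen import parse_newick, patristic_distances, pvr_eigenvectors
from crypsis.synthetic_data import SimConfig, generate_yule_tree, simulate_dataset

from crypsis.synthetic_data import REFERENCE_TREE_NEWICK

# fixed 14-taxon ultrametric tree used for PSR / selection tests
FOURTEEN_TAXON_NEWICK = REFERENCE_TREE_NEWICK


@pytest.fixture(scope="session")
def tree14():
    return parse_newick(FOURTEEN_TAXON_NEWICK)


@pytest.fixture(scope="session")
def basis14(tree14):
    return pvr_eigenvectors(patristic_distances(tree14))


@pytest.fixture(scope="session")
def yule10():
    return generate_yule_tree(10, birth_rate=1.0, seed=7)


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded draw of the default synthetic study (460 specimens)."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
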