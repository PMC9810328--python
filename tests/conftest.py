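import numpy as np
import pytest

from oncoclade import phylo, simulate


@pytest.fixture
def cherry():
    return phylo.read_newick("(A:1,B:2);")


@pytest.fixture
def basic_tree():
    return phylo.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_taxon_tree():
    return phylo.read_newick("((A:1,B:2):1,(C:1.5,D:0.5):2);")


def random_tree(seed: int, n_tips: int = 5, death: float = 0.0) -> phylo.TimeTree:
    """Small random time tree for property tests."""
    return simulate.simulate_tree(
        simulate.TreeParams(n_tips=n_tips, death=death), seed=seed
    )


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
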