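import numpy as np
import pytest

from karyoevol.simulate import sim_bd_tree
from karyoevol.trees import read_newick


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tip():
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def bd_tree_50():
    return sim_bd_tree(50, 1.0, 0.0, seed=7)


@pytest.fixture(scope="session")
def bd_tree_100():
    return sim_bd_tree(100, 1.0, 0.0, seed=11)


def random_trees(n_trees, n_tips, seed0):
    return [sim_bd_tree(n_tips, 1.0, 0.0, seed=seed0 + i)
            for i in range(n_trees)]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
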