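import numpy as np
import pytest

from songevo.phylo_core import parse_newick
from songevo.synthetic_data import simulate_yule


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def five_tip_tree():
    return parse_newick("((A:0.5,B:1.2):0.4,(C:0.7,(D:0.3,E:0.9):0.2):0.6);")


@pytest.fixture
def yule50():
    return simulate_yule(50, seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_tree(n_tips: int, seed: int):
    """Small random tree helper shared by the oracle tests."""
    return simulate_yule(n_tips, seed=seed)
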