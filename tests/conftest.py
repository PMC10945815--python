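import numpy as np
import pytest

from phylometab import synthetic_data as sd
from phylometab import treeio


@pytest.fixture
def three_tip_tree():
    return treeio.read_newick("((A:1,B:2):1,C:4);")


@pytest.fixture
def star_tree():
    return treeio.read_newick("(A:1,B:1,C:1,D:1);")


@pytest.fixture
def small_dataset():
    """One fixed synthetic study with both channels and planted effects."""
    return sd.simulate_dataset(sd.SimulationConfig(seed=7))


@pytest.fixture
def null_config():
    """Generator configuration with no domestication effect at all."""
    return sd.SimulationConfig(shift_effect=0.0, dom_rate_scale=1.0,
                               n_traits_untargeted=1)


def random_trees(n, n_tips=8, seed=0):
    rng = np.random.default_rng(seed)
    return [
        sd.simulate_tree(int(rng.integers(3, n_tips + 1)), int(rng.integers(2**31)))
        for _ in range(n)
    ]
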