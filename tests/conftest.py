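import numpy as np
import pytest

from iridisim.phylostats import load_tree
from iridisim.synth import gen_tree


@pytest.fixture(scope="session")
def star_tree_40():
    nwk = "(" + ",".join(f"t{i}:1.0" for i in range(40)) + ");"
    return load_tree(nwk)


@pytest.fixture(scope="session")
def yule_tree_64():
    return gen_tree(64, birth_rate=1.0, seed=7)


@pytest.fixture(scope="session")
def yule_tree_128():
    return gen_tree(128, birth_rate=1.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
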