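import numpy as np
import pytest

from linkdiffuse.netio import Network
from linkdiffuse.fixtures import random_connected_network


@pytest.fixture
def k2() -> Network:
    """Single edge."""
    return Network(["x", "y"], {(0, 1): 1.0})


@pytest.fixture
def triangle() -> Network:
    return Network(["a", "b", "c"], {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0})


@pytest.fixture
def path3() -> Network:
    """Path a-b-c."""
    return Network(["a", "b", "c"], {(0, 1): 1.0, (1, 2): 1.0})


@pytest.fixture
def path4() -> Network:
    """Path a-b-c-d."""
    return Network(["a", "b", "c", "d"], {(0, 1): 1.0, (1, 2): 1.0, (2, 3): 1.0})


def seeded_graphs(count: int, n: int = 20, m: int = 40, start_seed: int = 0):
    """A reproducible batch of random connected test graphs."""
    return [random_connected_network(n, m, seed) for seed in range(start_seed, start_seed + count)]
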