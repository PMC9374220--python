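import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from bridesnet.genio import GenotypeTable
from bridesnet.synth import fixture_toy_graphs, random_weighted_graph


@pytest.fixture(scope="session")
def toy():
    return fixture_toy_graphs()


@pytest.fixture()
def rng():
    return np.random.default_rng(20220812)


@pytest.fixture()
def small_table():
    """Two populations, two loci, one missing call, hand-enumerable."""
    calls = np.array(
        [
            [[1, 2], [1, 1]],
            [[1, 1], [1, 2]],
            [[2, 2], [0, 0]],
            [[1, 2], [2, 2]],
            [[2, 2], [2, 2]],
            [[1, 2], [1, 2]],
        ]
    )
    return GenotypeTable(
        individuals=[f"ind{i}" for i in range(6)],
        populations=["north"] * 3 + ["south"] * 3,
        loci=["locA", "locB"],
        calls=calls,
    )


def random_connected(rng, n_max=8, density=0.45):
    n = int(rng.integers(3, n_max + 1))
    seed = int(rng.integers(0, 2**31 - 1))
    return random_weighted_graph(n, density, seed=seed, connected=True)


@pytest.fixture()
def random_connected_factory(rng):
    return lambda **kw: random_connected(rng, **kw)
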