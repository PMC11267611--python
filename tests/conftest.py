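import numpy as np
import pytest
from hypothesis import settings

from strainlfer import MolecularGraph

# Reproducible hypothesis runs: the suite derives every example from the
# test's own structure, never from ambient entropy.
settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")

#: [1.1.1]propellane heavy-atom connectivity: bridgeheads 0 and 1 bonded to
#: each other and to three methylene bridges (2, 3, 4).
PROPELLANE_ATOMS = ["C", "C", "C", "C", "C"]
PROPELLANE_BONDS = [(0, 1), (0, 2), (1, 2), (0, 3), (1, 3), (0, 4), (1, 4)]


@pytest.fixture
def propellane() -> MolecularGraph:
    return MolecularGraph.from_adjacency(PROPELLANE_ATOMS, PROPELLANE_BONDS)


def random_graph(rng: np.random.Generator, n_nodes: int, p_edge: float) -> MolecularGraph:
    """Erdos-Renyi-style simple graph for oracle comparisons."""
    bonds = [
        (i, j)
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_edge
    ]
    return MolecularGraph.from_adjacency(["C"] * n_nodes, bonds)
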