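import numpy as np
import pytest

from gbanet.labels import GeneSet, GeneSetCollection
from gbanet.network import GeneNetwork, from_edges
from gbanet.synthetic import SyntheticSpec, generate_collection, generate_network


@pytest.fixture
def triangle() -> GeneNetwork:
    return from_edges("triangle", [("1", "2", 1.0), ("2", "3", 1.0), ("1", "3", 1.0)])


@pytest.fixture
def two_node() -> GeneNetwork:
    return from_edges("pair", [("10", "20", 2.0)])


def random_network(n_nodes: int, seed: int, p: float = 0.3, name: str = "rand") -> GeneNetwork:
    """Connected-ish Erdos–Renyi fixture with random weights; a spanning
    chain guarantees every node is an edge endpoint."""
    rng = np.random.default_rng(seed)
    genes = [str(100 + i) for i in range(n_nodes)]
    edges = [(genes[i], genes[i + 1], float(rng.uniform(0.2, 2.0))) for i in range(n_nodes - 1)]
    for i in range(n_nodes):
        for j in range(i + 2, n_nodes):
            if rng.random() < p:
                edges.append((genes[i], genes[j], float(rng.uniform(0.2, 2.0))))
    return from_edges(f"{name}{seed}", edges)


@pytest.fixture
def sbm_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=0)


@pytest.fixture
def sbm_network(sbm_spec) -> GeneNetwork:
    return generate_network(sbm_spec)


@pytest.fixture
def sbm_collection(sbm_spec, sbm_network) -> GeneSetCollection:
    return generate_collection(sbm_network, sbm_spec)


@pytest.fixture
def toy_collection() -> GeneSetCollection:
    """Universe g1..g10 with one 3-gene set overlapping positives {g1, g2}."""
    sets = (
        GeneSet("S1", "overlapping", frozenset({"1", "2", "3"})),
        GeneSet("S2", "rest", frozenset(str(i) for i in range(1, 11))),
    )
    return GeneSetCollection("toy", sets)
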