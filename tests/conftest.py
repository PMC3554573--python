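import networkx as nx
import numpy as np
import pytest

from netres.networks import BinaryNetwork, CorrelationMatrix


@pytest.fixture
def star4() -> BinaryNetwork:
    """Star with 4 leaves (center = node 0)."""
    return BinaryNetwork(nx.star_graph(4))


@pytest.fixture
def path3() -> BinaryNetwork:
    return BinaryNetwork(nx.path_graph(3))


@pytest.fixture
def k3() -> BinaryNetwork:
    return BinaryNetwork(nx.complete_graph(3))


def random_binary(n: int, p: float, seed: int) -> BinaryNetwork:
    return BinaryNetwork(nx.erdos_renyi_graph(n, p, seed=seed))


@pytest.fixture
def toy_corr() -> CorrelationMatrix:
    """3-node matrix with r12=0.9, r13=0.2, r23=0.5."""
    m = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.5], [0.2, 0.5, 1.0]])
    return CorrelationMatrix(m, ["a", "b", "c"])
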