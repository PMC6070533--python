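import networkx as nx
import numpy as np
import pytest

from s2b import Network


@pytest.fixture
def path3() -> Network:
    """A - B - C path."""
    return Network.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def k4() -> Network:
    return Network(nx.relabel_nodes(nx.complete_graph(4), lambda v: f"v{v}"))


def random_network(n: int, p: float, seed: int) -> Network:
    g = nx.gnp_random_graph(n, p, seed=seed)
    return Network(nx.relabel_nodes(g, {v: f"v{v:03d}" for v in g.nodes}))


@pytest.fixture
def small_scale_free() -> Network:
    g = nx.barabasi_albert_graph(120, 3, seed=5)
    return Network(nx.relabel_nodes(g, {v: f"v{v:03d}" for v in g.nodes}))
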