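import io

import networkx as nx
import pytest

from dca import SyntheticConfig, generate_benchmark


def graph_from_edges(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


@pytest.fixture
def triangle():
    return graph_from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def benchmark():
    """Default synthetic benchmark, seed 1."""
    return generate_benchmark(SyntheticConfig(seed=1))


def stream(text: str) -> io.StringIO:
    return io.StringIO(text)
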