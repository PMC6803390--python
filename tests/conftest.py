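import networkx as nx
import pytest


@pytest.fixture
def path4():
    return nx.path_graph(["A", "B", "C", "D"])


@pytest.fixture
def path5():
    return nx.path_graph(["A", "B", "C", "D", "E"])


@pytest.fixture
def two_cliques():
    """Two 5-cliques joined by a single edge."""
    g = nx.Graph()
    left = [f"L{i}" for i in range(5)]
    right = [f"R{i}" for i in range(5)]
    for group in (left, right):
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                g.add_edge(a, b)
    g.add_edge("L0", "R0")
    return g, set(left), set(right)
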