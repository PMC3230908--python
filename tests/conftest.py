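import networkx as nx
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def triangle_pair() -> nx.Graph:
    """Two disjoint unit-weight triangles."""
    g = nx.Graph()
    for tri in (("a", "b", "c"), ("x", "y", "z")):
        for i in range(3):
            g.add_edge(tri[i], tri[(i + 1) % 3], weight=1.0)
    return g


@pytest.fixture
def bridged_cliques() -> nx.Graph:
    """Two unit-weight 4-cliques joined by one weak bridge (weight 0.01)."""
    g = nx.Graph()
    left, right = ["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]
    for group in (left, right):
        for i, u in enumerate(group):
            for v in group[i + 1 :]:
                g.add_edge(u, v, weight=1.0)
    g.add_edge("a1", "b1", weight=0.01)
    return g
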