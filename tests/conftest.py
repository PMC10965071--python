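import networkx as nx
import pytest

from zentropy import make_fixture_graph


@pytest.fixture(scope="session")
def random_graphs() -> list[nx.Graph]:
    """100 seeded Erdős–Rényi graphs with at least one edge each."""
    graphs = []
    seed = 0
    while len(graphs) < 100:
        g = make_fixture_graph(n_vertices=12 + seed % 9, edge_prob=0.15 + 0.05 * (seed % 5), seed=seed)
        seed += 1
        if g.number_of_edges() > 0:
            # weight rules need degree >= 1 on both endpoints of every edge,
            # which any edge guarantees; isolated vertices are harmless
            graphs.append(g)
    return graphs


@pytest.fixture
def triangle() -> nx.Graph:
    g = nx.Graph()
    nx.add_cycle(g, ["a", "b", "c"])
    return g
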