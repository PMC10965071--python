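"""Seeded synthetic-graph fixtures.

Random Erdős–Rényi graphs used as oracle inputs throughout the test suite;
fully determined by the seed so every run is reproducible.
"""

from __future__ import annotations

import networkx as nx

__all__ = ["make_fixture_graph"]


def make_fixture_graph(n_vertices: int, edge_prob: float, seed: int) -> nx.Graph:
    """G(n, p) random graph with string vertex labels ``v0 .. v{n-1}``.

    Deterministic for a given seed; ``edge_prob = 1`` yields the complete
    graph.
    """
    if n_vertices < 1:
        raise ValueError(f"need at least one vertex, got {n_vertices}")
    if not (0 < edge_prob <= 1):
        raise ValueError(f"edge probability must be in (0, 1], got {edge_prob}")
    g = nx.gnp_random_graph(n_vertices, edge_prob, seed=seed)
    return nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes()})
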