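"""Molecular-graph container, degree bookkeeping, and the CuF₂(m, n) sheet lattice.

The copper(II) fluoride sheet is abstracted as a simple undirected graph whose
vertices are ions and whose edges are coordination bonds.  Growing the sheet
``m`` units horizontally and ``n`` units vertically yields a graph family
``CuF₂(m, n)`` with exactly ``12mn`` edges, partitioned by the unordered pair
of endpoint degrees into three classes:

=============  =====================
degree pair    number of edges
=============  =====================
(1, 3)         ``2m + 2n + 2``
(2, 3)         ``4m + 4n − 8``
(3, 3)         ``12mn − 6m − 6n + 6``
=============  =====================

Only this combinatorial structure is modelled — no 3D coordinates, bond
lengths or polymorph chemistry.  Graphs are :class:`networkx.Graph` instances
throughout; helpers here enforce the simple-graph contract (no self-loops,
no parallel edges) and provide plain-text edge-list I/O.
"""

from __future__ import annotations

import os
from collections import Counter
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "CUF2_DEGREE_PAIRS",
    "validate_graph",
    "compute_degrees",
    "edge_partition",
    "cuf2_partition_counts",
    "cuf2_vertex_count",
    "build_cuf2_lattice",
    "read_edge_list",
    "write_edge_list",
    "write_graphml",
]

#: the three degree classes of the CuF₂ family, sorted as (min, max)
CUF2_DEGREE_PAIRS: tuple[tuple[int, int], ...] = ((1, 3), (2, 3), (3, 3))


class EdgeListParseError(ValueError):
    """Raised when an edge-list file contains a malformed or invalid line."""


def _check_lattice_params(m: int, n: int) -> None:
    if not (isinstance(m, int) and isinstance(n, int)):
        raise TypeError(f"lattice parameters must be integers, got m={m!r}, n={n!r}")
    if m < 1 or n < 1:
        raise ValueError(f"lattice parameters require m, n >= 1, got m={m}, n={n}")


def validate_graph(g: nx.Graph) -> nx.Graph:
    """Check the simple-graph contract and return ``g`` unchanged.

    ``networkx.Graph`` already collapses parallel edges, so only self-loops
    (and directedness) need rejecting.
    """
    if g.is_directed() or g.is_multigraph():
        raise ValueError("expected a simple undirected networkx.Graph")
    loops = list(nx.selfloop_edges(g))
    if loops:
        raise ValueError(f"self-loops are not allowed: {sorted(map(str, {u for u, _ in loops}))}")
    return g


def compute_degrees(g: nx.Graph) -> dict:
    """Map every vertex of ``g`` to its incident-edge count (Λ_u)."""
    validate_graph(g)
    return dict(g.degree())


def edge_partition(g: nx.Graph) -> Counter:
    """Tally edges of ``g`` by the unordered pair of endpoint degrees.

    Returns a counter keyed by ``(min_degree, max_degree)``; the counts sum
    to ``|E(g)|``.
    """
    deg = compute_degrees(g)
    tally: Counter = Counter()
    for u, v in g.edges():
        a, b = deg[u], deg[v]
        tally[(a, b) if a <= b else (b, a)] += 1
    return tally


def cuf2_partition_counts(m: int, n: int) -> dict[tuple[int, int], int]:
    """Edge-class counts of CuF₂(m, n) from the partition polynomials.

    The three counts sum to ``12mn`` for every ``m, n >= 1``.
    """
    _check_lattice_params(m, n)
    return {
        (1, 3): 2 * m + 2 * n + 2,
        (2, 3): 4 * m + 4 * n - 8,
        (3, 3): 12 * m * n - 6 * m - 6 * n + 6,
    }


def cuf2_vertex_count(m: int, n: int) -> int:
    """Order of CuF₂(m, n): ``8mn + 2m + 2n`` (from the degree multiset)."""
    _check_lattice_params(m, n)
    return 8 * m * n + 2 * m + 2 * n


def build_cuf2_lattice(m: int, n: int) -> nx.Graph:
    """Construct an explicit realization of the CuF₂(m, n) sheet.

    The sheet is tiled as an ``m × n`` grid of 6-cycles ("hexagon units",
    vertices ``h{i}_{j}_{t}``, ``t = 0..5``).  Every hexagon vertex receives
    exactly one external attachment, so all ring vertices end up with degree
    3 and every ring edge is a (3, 3) edge:

    * interior junctions ``x{i}_{j}_{a|b}`` — two degree-3 vertices in each
      of the ``(m−1)(n−1)`` interior gaps, each bonded to three hexagon
      vertices of the four surrounding units (2 slots of the lower-left and
      upper-right units, 1 slot of the other two);
    * boundary bridges ``s{b|t|l|r}{k}`` — one degree-2 vertex joining the
      two units of each column gap along the bottom and top rows and of each
      row gap along the left and right columns, ``2(m−1) + 2(n−1)`` in all;
    * pendants ``q{i}_{j}_{t}`` on every remaining slot, ``2m + 2n + 2``
      in all.

    The result is simple and connected, has ``12mn`` edges and
    ``8mn + 2m + 2n`` vertices, and its :func:`edge_partition` equals
    :func:`cuf2_partition_counts` exactly.  Labels are deterministic, so the
    build is reproducible.
    """
    _check_lattice_params(m, n)
    g = nx.Graph()

    slots: dict[tuple[int, int], int] = {}
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            ring = [f"h{i}_{j}_{t}" for t in range(6)]
            nx.add_cycle(g, ring)
            slots[(i, j)] = 0

    def take(i: int, j: int) -> str:
        # next free attachment slot of hexagon (i, j); each unit has 6
        t = slots[(i, j)]
        if t >= 6:  # pragma: no cover - guarded by the slot accounting
            raise RuntimeError(f"hexagon ({i}, {j}) over-allocated")
        slots[(i, j)] = t + 1
        return f"h{i}_{j}_{t}"

    # interior junctions
    for i in range(1, m):
        for j in range(1, n):
            a, b = f"x{i}_{j}_a", f"x{i}_{j}_b"
            g.add_edge(a, take(i, j))
            g.add_edge(a, take(i + 1, j + 1))
            g.add_edge(a, take(i + 1, j))
            g.add_edge(b, take(i, j))
            g.add_edge(b, take(i + 1, j + 1))
            g.add_edge(b, take(i, j + 1))

    # boundary bridges: column gaps on bottom (j=1) and top (j=n) rows
    for i in range(1, m):
        g.add_edge(f"sb{i}", take(i, 1))
        g.add_edge(f"sb{i}", take(i + 1, 1))
        g.add_edge(f"st{i}", take(i, n))
        g.add_edge(f"st{i}", take(i + 1, n))
    # row gaps on left (i=1) and right (i=m) columns
    for j in range(1, n):
        g.add_edge(f"sl{j}", take(1, j))
        g.add_edge(f"sl{j}", take(1, j + 1))
        g.add_edge(f"sr{j}", take(m, j))
        g.add_edge(f"sr{j}", take(m, j + 1))

    # pendants fill every remaining slot
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            while slots[(i, j)] < 6:
                t = slots[(i, j)]
                g.add_edge(f"q{i}_{j}_{t}", take(i, j))

    return g


def read_edge_list(path: str | os.PathLike) -> nx.Graph:
    """Read a simple graph from a whitespace-separated edge-list file.

    One edge per line as ``u v``; ``#`` starts a comment; blank lines are
    skipped.  Duplicate lines collapse to a single edge.  Self-loops and
    lines without exactly two tokens raise :class:`EdgeListParseError`
    naming the offending line.
    """
    g = nx.Graph()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected two vertex labels, got {len(tokens)}: {raw.rstrip()!r}"
                )
            u, v = tokens
            if u == v:
                raise EdgeListParseError(f"{path}:{lineno}: self-loop {u!r}-{v!r} is not allowed")
            g.add_edge(u, v)
    return g


def write_edge_list(g: nx.Graph, path: str | os.PathLike) -> None:
    """Write ``g`` as a sorted whitespace-separated edge list (round-trips with
    :func:`read_edge_list`)."""
    validate_graph(g)
    with open(path, "wt", encoding="utf-8") as fh:
        for u, v in sorted((str(u), str(v)) if str(u) <= str(v) else (str(v), str(u)) for u, v in g.edges()):
            fh.write(f"{u} {v}\n")


def write_graphml(g: nx.Graph, path: str | os.PathLike) -> None:
    """Export ``g`` as undirected GraphML for interoperability."""
    validate_graph(g)
    nx.write_graphml(g, path)
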