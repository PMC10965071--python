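"""Similarity-network inference over descriptor/entropy datasets.

Given a variables × observations data matrix X, each variable pair (i, j)
is scored by a signed blend of Pearson correlation ϖ and Euclidean distance
ν between the two row profiles::

    S_ij = sign(ϖ_ij) · ( |ϖ_ij| + (1 − ln(ν_ij + 1) / max ln(ν + 1)) ) / 2

where the max runs over all off-diagonal pairs of the same matrix.  Both
terms lie in [0, 1], so S ∈ [−1, 1]: values near 1 flag highly positively
related variables, values near −1 strong dissimilarity, and identical rows
score exactly 1.

The similarity matrix is sharpened into a soft-threshold adjacency
``A_ij = |S_ij|^β`` (zero diagonal), edges with ``A_ij ≥ τ`` are kept, and
the connected components of the resulting graph are the variable clusters.
Two networks built from different datasets over the same variables (e.g.
the twelve index series vs the twelve entropy series of the CuF₂ family)
can be compared by edge-set Jaccard index and component-partition equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .descriptors import WEIGHT_NAMES, index_closed_form
from .entropy import entropy_closed_form

__all__ = [
    "Network",
    "TopologyComparison",
    "family_dataset",
    "similarity_matrix",
    "adjacency_from_similarity",
    "network_from_adjacency",
    "compare_topology",
]


@dataclass(frozen=True)
class Network:
    """Thresholded variable network: weighted edges plus its cluster partition."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]  # (u, v, adjacency weight), u < v
    components: tuple[frozenset, ...]

    def edge_set(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v, _ in self.edges}

    def partition(self) -> set[frozenset]:
        return set(self.components)


@dataclass(frozen=True)
class TopologyComparison:
    """Agreement report between two networks on the same node set."""

    jaccard: float
    same_partition: bool
    n_edges_1: int
    n_edges_2: int
    n_shared_edges: int


def family_dataset(kind: str, kmin: int = 1, kmax: int = 8) -> pd.DataFrame:
    """The 'indices' or 'entropy' data matrix of the CuF₂ family.

    Twelve variables (the descriptor names) × observations k = kmin..kmax
    (square lattices m = n = k).
    """
    if kind not in ("indices", "entropy"):
        raise ValueError(f"kind must be 'indices' or 'entropy', got {kind!r}")
    ks = list(range(kmin, kmax + 1))
    if kind == "indices":
        values = [[index_closed_form(k, k, nm).value for k in ks] for nm in WEIGHT_NAMES]
    else:
        values = [[entropy_closed_form(k, k, nm).value for k in ks] for nm in WEIGHT_NAMES]
    return pd.DataFrame(values, index=pd.Index(WEIGHT_NAMES, name="variable"), columns=[f"k={k}" for k in ks])


def similarity_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Pearson–Euclidean similarity between the row variables of ``data``.

    Requires at least 2 variables and 2 observations, no missing values and
    no zero-variance row (the correlation would be undefined — the offending
    variable is named in the error).  Returns a symmetric matrix with unit
    diagonal and values in [−1, 1].
    """
    values = np.asarray(data, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 variables and >= 2 observations")
    if np.isnan(values).any():
        raise ValueError("data matrix contains missing values")
    variables = [str(v) for v in data.index]
    stds = values.std(axis=1)
    dead = [variables[i] for i in np.flatnonzero(stds == 0)]
    if dead:
        raise ValueError(f"zero-variance variable(s) make correlation undefined: {dead}")

    rho = np.corrcoef(values)
    rho = np.clip(rho, -1.0, 1.0)
    dist = squareform(pdist(values, metric="euclidean"))
    logd = np.log(dist + 1.0)
    off = ~np.eye(len(variables), dtype=bool)
    max_logd = logd[off].max()
    if max_logd == 0.0:  # all rows identical: every pair is maximally similar
        scaled = np.ones_like(logd)
    else:
        scaled = 1.0 - logd / max_logd
    s = np.sign(rho) * (np.abs(rho) + scaled) / 2.0
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(s, index=data.index.copy(), columns=data.index.copy())


def adjacency_from_similarity(similarity: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Soft-threshold adjacency ``A = |S|^β`` with zero diagonal.

    ``β >= 1`` sharpens the contrast: since |S| ≤ 1, larger β pushes weak
    similarities towards 0 while near-perfect ones survive.
    """
    if beta < 1:
        raise ValueError(f"power must satisfy beta >= 1, got {beta}")
    a = np.abs(np.asarray(similarity, dtype=float)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=similarity.index.copy(), columns=similarity.columns.copy())


def network_from_adjacency(adjacency: pd.DataFrame, tau: float = 0.1) -> Network:
    """Keep edges with adjacency ≥ τ and extract connected components."""
    if not (0 <= tau < 1):
        raise ValueError(f"threshold must satisfy 0 <= tau < 1, got {tau}")
    nodes = [str(v) for v in adjacency.index]
    a = np.asarray(adjacency, dtype=float)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if a[i, j] >= tau:
                g.add_edge(nodes[i], nodes[j], weight=float(a[i, j]))
    edges = tuple(
        sorted((min(u, v), max(u, v), float(d["weight"])) for u, v, d in g.edges(data=True))
    )
    components = tuple(sorted((frozenset(c) for c in nx.connected_components(g)), key=lambda c: sorted(c)))
    return Network(nodes=tuple(nodes), edges=edges, components=components)


def compare_topology(n1: Network, n2: Network) -> TopologyComparison:
    """Edge-set Jaccard index and partition agreement of two networks."""
    if set(n1.nodes) != set(n2.nodes):
        raise ValueError("networks are defined on different node sets")
    e1, e2 = n1.edge_set(), n2.edge_set()
    union = e1 | e2
    shared = e1 & e2
    jaccard = 1.0 if not union else len(shared) / len(union)
    return TopologyComparison(
        jaccard=jaccard,
        same_partition=n1.partition() == n2.partition(),
        n_edges_1=len(e1),
        n_edges_2=len(e2),
        n_shared_edges=len(shared),
    )
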