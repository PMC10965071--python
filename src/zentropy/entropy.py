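"""Shannon entropy of an edge-weighted graph.

For a graph ``G`` with strictly positive edge weights ``w(e)`` and total
weight ``W = Σ_e w(e)``, the edge-weight entropy is the Shannon entropy of
the normalised weight distribution (natural logarithm, value in nats)::

    H = − Σ_e (w(e)/W)·ln(w(e)/W)  =  ln W − (Σ_e w(e)·ln w(e)) / W

It is invariant under scaling all weights by a constant, non-negative, and
at most ``ln |E(G)|`` with equality exactly when all weights coincide.

Applied to the twelve hybrid Zagreb weight rules on the CuF₂(m, n) family,
the edge partition reduces the sum to the three degree classes, giving a
closed form in ``(m, n)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .descriptors import WEIGHT_NAMES, _check_name, edge_weight
from .graph_core import compute_degrees, cuf2_partition_counts, edge_partition

__all__ = [
    "EntropyValue",
    "shannon_entropy",
    "entropy_from_graph",
    "entropy_closed_form",
    "entropy_table",
]


@dataclass(frozen=True)
class EntropyValue:
    """An entropy value (nats) with its provenance."""

    name: str
    value: float
    provenance: str  # "graph-sum" | "closed-form"


def shannon_entropy(weights: Sequence[float]) -> float:
    """Entropy (nats) of the distribution obtained by normalising ``weights``.

    Computed in the rearranged form ``ln W − Σ w·ln w / W``, which avoids
    forming the probabilities explicitly.  All weights must be positive.
    """
    weights = list(weights)
    if not weights:
        raise ValueError("entropy is undefined for an empty weight set")
    if any(w <= 0 for w in weights):
        raise ValueError("all edge weights must be strictly positive")
    total = math.fsum(weights)
    wlogw = math.fsum(w * math.log(w) for w in weights)
    return math.log(total) - wlogw / total


def entropy_from_graph(g: nx.Graph, name: str) -> EntropyValue:
    """Edge-weight entropy of ``g`` under weight rule ``name``.

    Edges are grouped by degree class first; within a class all weights are
    equal, so the entropy sum collapses to one term per class.
    """
    _check_name(name)
    if g.number_of_edges() == 0:
        raise ValueError("entropy is undefined on a graph with no edges")
    cw = [(c, edge_weight(name, a, b)) for (a, b), c in edge_partition(g).items()]
    total = math.fsum(c * w for c, w in cw)
    wlogw = math.fsum(c * w * math.log(w) for c, w in cw)
    return EntropyValue(name=name, value=math.log(total) - wlogw / total, provenance="graph-sum")


def entropy_closed_form(m: int, n: int, name: str) -> EntropyValue:
    """Edge-weight entropy of CuF₂(m, n) from the partition closed form.

    ``H(m, n) = ln I(m, n) − [Σ_i c_i(m, n)·w_i·ln w_i] / I(m, n)`` with the
    three class counts ``c_i`` and exact class weights ``w_i``; ``I`` is the
    corresponding index.
    """
    _check_name(name)
    counts = cuf2_partition_counts(m, n)  # validates m, n
    cw = [(c, edge_weight(name, a, b)) for (a, b), c in counts.items() if c > 0]
    total = math.fsum(c * w for c, w in cw)
    wlogw = math.fsum(c * w * math.log(w) for c, w in cw)
    return EntropyValue(name=name, value=math.log(total) - wlogw / total, provenance="closed-form")


def entropy_table(
    ks: Iterable[int] = range(1, 7),
    names: Sequence[str] = WEIGHT_NAMES,
) -> pd.DataFrame:
    """Closed-form entropies on square lattices m = n = k.

    Rows are ``ENT_<name>``, columns ``[k, k]`` — the layout of the
    comparative entropy table.
    """
    ks = list(ks)
    names = list(names)
    if not ks or not names:
        raise ValueError("need at least one k value and one index name")
    for name in names:
        _check_name(name)
    data = {f"[{k}, {k}]": [entropy_closed_form(k, k, nm).value for nm in names] for k in ks}
    return pd.DataFrame(data, index=pd.Index([f"ENT_{nm}" for nm in names], name="entropy"))
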