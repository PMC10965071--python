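"""Independent brute-force reference implementations.

Everything here is coded directly from the defining formulas, without using
any zentropy internals, so the package can be checked against a second,
independently written path:

* degrees via adjacency-matrix row sums,
* indices via an explicit per-edge loop,
* entropy via the probability form  −Σ p·ln p,
* the log model via hand-rolled normal equations.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

# per-edge weight rules, written out longhand (a, b are endpoint degrees)
ORACLE_RULES = {
    "BM": lambda a, b: a + b + a * b,
    "TM": lambda a, b: a * a + b * b + a * b,
    "GBM": lambda a, b: math.sqrt(a * b) / (a + b + a * b),
    "GTM": lambda a, b: math.sqrt(a * b) / (a * a + b * b + a * b),
    "GH": lambda a, b: math.sqrt(a * b) * (a + b) / 2.0,
    "HBM": lambda a, b: 2.0 / ((a + b + a * b) * (a + b)),
    "HTM": lambda a, b: 2.0 / ((a * a + b * b + a * b) * (a + b)),
    "HG": lambda a, b: 2.0 / (math.sqrt(a * b) * (a + b)),
    "BMH": lambda a, b: (a + b + a * b) * (a + b) / 2.0,
    "BMG": lambda a, b: (a + b + a * b) / math.sqrt(a * b),
    "TMH": lambda a, b: (a * a + b * b + a * b) * (a + b) / 2.0,
    "TMG": lambda a, b: (a * a + b * b + a * b) / math.sqrt(a * b),
}


def oracle_degrees(g: nx.Graph) -> dict:
    """Vertex degrees as adjacency-matrix row sums."""
    nodes = list(g.nodes())
    a = nx.to_numpy_array(g, nodelist=nodes)
    return {v: int(s) for v, s in zip(nodes, a.sum(axis=1))}


def oracle_edge_partition(g: nx.Graph) -> dict:
    """Per-edge tally of sorted endpoint-degree pairs."""
    deg = oracle_degrees(g)
    out: dict = {}
    for u, v in g.edges():
        key = tuple(sorted((deg[u], deg[v])))
        out[key] = out.get(key, 0) + 1
    return out


def oracle_edge_weights(g: nx.Graph, name: str) -> list[float]:
    deg = oracle_degrees(g)
    return [ORACLE_RULES[name](deg[u], deg[v]) for u, v in g.edges()]


def oracle_index(g: nx.Graph, name: str) -> float:
    """Index as a plain per-edge double loop over the weight rule."""
    return sum(oracle_edge_weights(g, name))


def oracle_entropy(g: nx.Graph, name: str) -> float:
    """Entropy via the normalised probability distribution, term by term."""
    w = np.array(oracle_edge_weights(g, name))
    p = w / w.sum()
    return float(-(p * np.log(p)).sum())


def oracle_log_fit(x, y) -> dict:
    """y = a·ln x + b by explicit normal equations, plus R² and F."""
    t = np.log(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    n = len(t)
    sxx = ((t - t.mean()) ** 2).sum()
    sxy = ((t - t.mean()) * (y - y.mean())).sum()
    a = sxy / sxx
    b = y.mean() - a * t.mean()
    resid = y - (a * t + b)
    rss = (resid**2).sum()
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - rss / tss
    return {"a": a, "b": b, "r2": r2, "ss_reg": tss - rss, "f": (tss - rss) / (rss / (n - 2))}
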