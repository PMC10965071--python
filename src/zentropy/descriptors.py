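"""The twelve hybrid Zagreb edge-weight descriptors.

Each descriptor is a degree-based topological index: a sum over the edges of
a molecular graph of a positive weight that depends only on the endpoint
degrees ``(a, b)``.  With the shorthands ``s = a + b`` (degree sum),
``p = a·b`` (degree product) and ``q = a² + b²``, the twelve rules are

====  =====================  ====  =====================
name  weight w(a, b)         name  weight w(a, b)
====  =====================  ====  =====================
BM    s + p                  HBM   2 / ((s + p)·s)
TM    q + p                  HTM   2 / ((q + p)·s)
GBM   √p / (s + p)           HG    2 / (√p·s)
GTM   √p / (q + p)           BMH   (s + p)·s / 2
GH    √p·s / 2               BMG   (s + p) / √p
TMH   (q + p)·s / 2          TMG   (q + p) / √p
====  =====================  ====  =====================

BM and TM are the "bi-" and "tri-Zagreb" weights; the other ten are hybrids
pairing them (and the geometric mean √p and half-sum s/2) in ratios.  Each
harmonic/geometric hybrid is the per-edge reciprocal of its partner:
``HBM·BMH = HTM·TMH = HG·GH = GBM·BMG = GTM·TMG = 1``.

On the CuF₂(m, n) family the edge partition collapses every index to an
exact closed form ``I(m, n) = c_mn·mn + c_m·(m + n) + c_1`` whose
coefficients follow from the three class weights::

    c_mn = 12·w(3,3)
    c_m  = 2·w(1,3) + 4·w(2,3) − 6·w(3,3)
    c_1  = 2·w(1,3) − 8·w(2,3) + 6·w(3,3)

Coefficients are kept as exact rationals/surds (via sympy); numeric output
is float.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import sympy as sp

from .graph_core import compute_degrees, cuf2_partition_counts, edge_partition

__all__ = [
    "WEIGHT_NAMES",
    "IndexValue",
    "ClosedFormCoefficients",
    "edge_weight",
    "exact_edge_weight",
    "index_from_graph",
    "index_closed_form",
    "closed_form_coefficients",
    "index_table",
]

# rules written against a generic (a, b, sqrt) so the same table serves the
# float engine (math.sqrt) and the exact engine (sympy.sqrt)
_RULES: dict[str, Callable] = {
    "BM": lambda a, b, sqrt: (a + b) + a * b,
    "TM": lambda a, b, sqrt: (a**2 + b**2) + a * b,
    "GBM": lambda a, b, sqrt: sqrt(a * b) / ((a + b) + a * b),
    "GTM": lambda a, b, sqrt: sqrt(a * b) / ((a**2 + b**2) + a * b),
    "GH": lambda a, b, sqrt: sqrt(a * b) * (a + b) / 2,
    "HBM": lambda a, b, sqrt: 2 / (((a + b) + a * b) * (a + b)),
    "HTM": lambda a, b, sqrt: 2 / (((a**2 + b**2) + a * b) * (a + b)),
    "HG": lambda a, b, sqrt: 2 / (sqrt(a * b) * (a + b)),
    "BMH": lambda a, b, sqrt: ((a + b) + a * b) * (a + b) / 2,
    "BMG": lambda a, b, sqrt: ((a + b) + a * b) / sqrt(a * b),
    "TMH": lambda a, b, sqrt: ((a**2 + b**2) + a * b) * (a + b) / 2,
    "TMG": lambda a, b, sqrt: ((a**2 + b**2) + a * b) / sqrt(a * b),
}

#: canonical order of the twelve descriptor names
WEIGHT_NAMES: tuple[str, ...] = (
    "BM", "TM", "GBM", "GTM", "GH", "HBM",
    "HTM", "HG", "BMH", "BMG", "TMH", "TMG",
)


@dataclass(frozen=True)
class IndexValue:
    """A computed index value with its provenance (graph-sum or closed-form)."""

    name: str
    value: float
    provenance: str  # "graph-sum" | "closed-form"


@dataclass(frozen=True)
class ClosedFormCoefficients:
    """Exact closed-form coefficients of an index on the CuF₂ family.

    ``I(m, n) = coeff_mn·mn + coeff_m·m + coeff_n·n + coeff_1`` with
    ``coeff_m == coeff_n`` by the m/n symmetry of the partition polynomials.
    Attributes are exact sympy expressions (rationals and surds).
    """

    name: str
    coeff_mn: sp.Expr
    coeff_m: sp.Expr
    coeff_n: sp.Expr
    coeff_1: sp.Expr

    def as_floats(self) -> tuple[float, float, float, float]:
        return (
            float(self.coeff_mn),
            float(self.coeff_m),
            float(self.coeff_n),
            float(self.coeff_1),
        )

    def evaluate(self, m: int, n: int) -> float:
        c_mn, c_m, c_n, c_1 = self.as_floats()
        return c_mn * m * n + c_m * m + c_n * n + c_1


def _check_name(name: str) -> str:
    if name not in _RULES:
        raise KeyError(f"unknown index name {name!r}; choose one of {WEIGHT_NAMES}")
    return name


def edge_weight(name: str, a: int, b: int) -> float:
    """Weight of an edge with endpoint degrees ``(a, b)`` under rule ``name``.

    Symmetric in ``(a, b)`` and strictly positive for ``a, b >= 1``.
    """
    _check_name(name)
    if a < 1 or b < 1:
        raise ValueError(f"degrees must be >= 1, got ({a}, {b})")
    return float(_RULES[name](a, b, math.sqrt))


def exact_edge_weight(name: str, a: int, b: int) -> sp.Expr:
    """Exact (sympy) edge weight, used by the closed-form engine."""
    _check_name(name)
    if a < 1 or b < 1:
        raise ValueError(f"degrees must be >= 1, got ({a}, {b})")
    return sp.nsimplify(_RULES[name](sp.Integer(a), sp.Integer(b), sp.sqrt))


def index_from_graph(g: nx.Graph, name: str) -> IndexValue:
    """Sum the rule ``name`` over the edges of ``g``.

    The sum is grouped by degree class (via the edge partition), which is
    exactly equivalent to the per-edge sum but faster on large lattices.
    """
    _check_name(name)
    if g.number_of_edges() == 0:
        raise ValueError("index is undefined on a graph with no edges")
    total = 0.0
    for (a, b), count in edge_partition(g).items():
        total += count * edge_weight(name, a, b)
    return IndexValue(name=name, value=total, provenance="graph-sum")


@lru_cache(maxsize=None)
def closed_form_coefficients(name: str) -> ClosedFormCoefficients:
    """Exact closed-form coefficients of index ``name`` on CuF₂(m, n).

    Example: ``closed_form_coefficients("BM")`` gives (180, −32, −32, 16),
    i.e. BM(m, n) = 180mn − 32m − 32n + 16.
    """
    _check_name(name)
    w13 = exact_edge_weight(name, 1, 3)
    w23 = exact_edge_weight(name, 2, 3)
    w33 = exact_edge_weight(name, 3, 3)
    return ClosedFormCoefficients(
        name=name,
        coeff_mn=sp.simplify(12 * w33),
        coeff_m=sp.simplify(2 * w13 + 4 * w23 - 6 * w33),
        coeff_n=sp.simplify(2 * w13 + 4 * w23 - 6 * w33),
        coeff_1=sp.simplify(2 * w13 - 8 * w23 + 6 * w33),
    )


def index_closed_form(m: int, n: int, name: str) -> IndexValue:
    """Evaluate index ``name`` on CuF₂(m, n) from the partition closed form.

    Equivalent to multiplying each class count by its exact class weight and
    summing; agrees with :func:`index_from_graph` on the built lattice to
    float precision.
    """
    _check_name(name)
    counts = cuf2_partition_counts(m, n)  # validates m, n
    total = sum(c * edge_weight(name, a, b) for (a, b), c in counts.items())
    return IndexValue(name=name, value=total, provenance="closed-form")


def index_table(
    ks: Iterable[int] = range(1, 7),
    names: Sequence[str] = WEIGHT_NAMES,
) -> pd.DataFrame:
    """Closed-form index values on square lattices m = n = k.

    Rows are index names, columns are labelled ``[k, k]`` — the layout of the
    comparative index table.
    """
    ks = list(ks)
    names = list(names)
    if not ks or not names:
        raise ValueError("need at least one k value and one index name")
    for name in names:
        _check_name(name)
    data = {f"[{k}, {k}]": [index_closed_form(k, k, nm).value for nm in names] for k in ks}
    return pd.DataFrame(data, index=pd.Index(names, name="index"))
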