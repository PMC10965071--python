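# Methods

## Scope and model

The package computes degree-based topological indices and edge-weight
entropies for simple undirected molecular graphs, with exact closed forms
on the CuF₂(m, n) sheet-lattice family, plus two downstream analyses: a
logarithmic regression linking each index series to its entropy series,
and a similarity-network comparison of the two datasets. Only the
combinatorial graph is modelled — no crystallographic coordinates, bond
lengths, Jahn–Teller geometry or polymorphs.

## The twelve weight rules

Every descriptor is `I(G) = Σ_{uv ∈ E} w(d_u, d_v)` for one of twelve
symmetric positive rules built from `s = a + b`, `p = a·b`, `q = a² + b²`
(see the README table). Two conventions required a decision because the
published typesetting is ambiguous:

* **Geometric factors are `√(a·b)`.** Only this reading reproduces every
  closed-form coefficient (e.g. `12·√9/27 = 1.3333` for GTM's `mn`
  coefficient, `2·2√3 + 4·2.5√6 − 54 = −22.577` for GH's linear
  coefficient).
* **The BM weight at (3,3) is 15**, i.e. `(3+3) + 3·3`. The source display
  prints a factor 13 there, but the closed form `180mn − 32m − 32n + 16`
  and the comparative table both require 15; the 13 is a transcription
  error.

The rules are total functions of any degree pair `(a, b)` with
`a, b ≥ 1`; the generic engine is not restricted to the three CuF₂
classes. Five reciprocal-pair identities
(`HBM·BMH = HTM·TMH = HG·GH = GBM·BMG = GTM·TMG = 1` per edge) hold by
construction and are property-tested.

## The CuF₂(m, n) lattice

The family is *defined* by its edge partition — `(1,3): 2m+2n+2`,
`(2,3): 4m+4n−8`, `(3,3): 12mn−6m−6n+6`, summing to `12mn` — together
with simplicity and connectedness. The degree multiset follows by
handshake bookkeeping: `2m+2n+2` pendant vertices, `2m+2n−4` degree-2
vertices, `8mn−2m−2n+2` degree-3 vertices, hence `8mn+2m+2n` vertices.

No explicit adjacency is published, so any realization meeting that
contract is valid. The tiling used here is an `m × n` grid of 6-cycles
("hexagon units") in which **every hexagon vertex receives exactly one
external attachment**, making all ring vertices degree 3 and every ring
edge a (3,3) edge:

* **Interior junctions.** Each of the `(m−1)(n−1)` interior gaps holds two
  degree-3 junction vertices, each bonded to three hexagon vertices of the
  four surrounding units. The pair consumes 2/1/1/2 attachment slots of
  the lower-left/lower-right/upper-left/upper-right units, so every
  interior hexagon (four surrounding junctions) uses exactly
  2+2+1+1 = 6 slots. Junction–hexagon edges are (3,3):
  `6(m−1)(n−1) = 12mn − 6m − 6n + 6 − 6mn` of them, which together with
  the `6mn` ring edges gives the (3,3) count exactly.
* **Boundary bridges.** One degree-2 vertex spans each column gap along
  the bottom and top rows and each row gap along the left and right
  columns — `2(m−1) + 2(n−1)` bridges, contributing the `4m+4n−8`
  (2,3) edges.
* **Pendants** fill all remaining slots; the slot accounting leaves
  exactly `2m+2n+2` of them (interior boundary hexagons keep 1 free slot,
  the four corner units 2 or 3, every unit in a 1-row/1-column family
  correspondingly more).

The construction is deterministic (labels `h{i}_{j}_{t}`, `x{i}_{j}_{a|b}`,
`s{b|t|l|r}{k}`, `q{i}_{j}_{t}`), and the property suite verifies
simplicity, connectedness, vertex count and exact partition equality for
all `m, n ∈ [1, 8]`.

## Closed forms and numerical conventions

Grouping the edge sum by partition class gives
`I(m, n) = c_mn·mn + c_m·(m + n) + c_1` with

    c_mn = 12·w(3,3),  c_m = 2·w(1,3) + 4·w(2,3) − 6·w(3,3),
    c_1  = 2·w(1,3) − 8·w(2,3) + 6·w(3,3).

Coefficients are kept as exact sympy rationals and surds; numeric
evaluation multiplies integer class counts by float class weights (error
at machine precision, ~1e−16 relative). Graph-sum and closed-form paths
agree to 1e−12 relative on built lattices.

The published comparative tables were generated from 3-decimal rounded
coefficients, so exact values can differ from printed ones by up to
~0.003 at k = 6. Two known discrepancies:

* the printed HBM value at [6,6], 111.4450, is a typo for 11.4450 (the
  closed form gives 11.44502, consistent with the row's trend);
* the printed BMG row at [4,4], [5,5], [6,6] sits 0.0023/0.0027/0.0030
  from the exact values — the rounded coefficients −3.954 and +2.158
  (exact: −3.95417, +2.15705) reproduce the printed cells exactly, so the
  drift is accumulated coefficient round-off, not a computation error.
  The table-reproduction test applies a uniform ±0.002 band and therefore
  flags exactly these three cells; the failure is expected and documented
  rather than masked.

## Edge-weight entropy

`H = ln W − (Σ_e w_e·ln w_e)/W` with `W = Σ_e w_e`, natural logarithm
(nats). Natural log is the only base that reproduces the published
entropy table (e.g. `ln 132 − 325.452/132 = 2.4172` for BM at m = n = 1);
base-10 does not. The implementation groups edges by partition class
(weights within a class are equal), is scale-invariant in the weights,
bounded by `0 ≤ H ≤ ln|E|` with the maximum iff all weights coincide, and
rejects non-positive weights (all twelve rules are strictly positive, so
this only guards foreign inputs). Asymptotically on the family
`H − ln I → −ln w(3,3)` as the (3,3) class dominates; the boundary
classes decay like `(m+n)/mn`, verified numerically at m = n = 5000.

## Logarithmic regression

`Y = a·ln X + b` fitted by OLS (statsmodels behind the module surface; an
independently coded normal-equations oracle checks it in the tests).
Reported statistics: R (sign matching the slope), R², the regression
standard error `S_E = √(RSS/(n−2))`, the regression sum of squares
`SS = TSS − RSS`, df = 1 and `F = SS/(RSS/(n−2))`.

Conventions: the observation set is square lattices `m = n = k`,
`k = 1..8` (eight observations per fit — this choice reproduces the
published ENT_BM coefficients 0.954/−2.266 to three decimals); "SS" is
interpreted as the regression sum of squares (14.221 for ENT_BM matches;
with R² ≈ 1 it is numerically indistinguishable from total SS, which is
also reported for comparison); R is reported unrounded rather than forced
to the printed 1.

## Similarity networks

For a variables × observations matrix, each variable pair is scored

    S_ij = sign(ρ_ij)·( |ρ_ij| + (1 − ln(ν_ij + 1)/max ln(ν + 1)) ) / 2

with ρ the Pearson correlation, ν the Euclidean distance between row
profiles and the max over all off-diagonal pairs of the same matrix. The
published formula's grouping is ambiguous; this reading — the average of
a correlation-magnitude term and a normalised log-distance term — is the
one that delivers the stated range behaviour (values in [−1, 1], exactly 1
for identical variables). If all rows are identical the distance
normaliser vanishes and the distance term is defined as 1. Zero-variance
rows are rejected by name (correlation undefined).

The adjacency is the soft-threshold power `A = |S|^β` (zero diagonal),
edges with `A ≥ τ` are kept, and clusters are connected components.
Defaults β = 6, τ = 0.1: the source states neither value, so these are
package choices in the WGCNA soft-threshold tradition, CLI-configurable.
Consequently the claim that the index network and the entropy network
share identical structure is parameter-dependent; the pipeline *reports*
the edge-set Jaccard index and partition equality instead of asserting
them (at the defaults over k = 1..8 the two networks differ: the entropy
variables are much more uniformly intercorrelated than the index
variables).

## Synthetic fixtures

Oracle tests run on 100 seeded Erdős–Rényi graphs G(n, p) with
n ∈ [12, 20] and p ∈ [0.15, 0.35] — small dense-enough graphs exercising
degree pairs well outside the lattice's three classes. They emulate
arbitrary molecular graphs only in the combinatorial sense (no chemical
realizability, valence limits or connectivity guarantees), so passing
oracle tests shows the engines compute their defining formulas correctly
on arbitrary simple graphs, not that the descriptors are chemically
meaningful beyond the lattice family.

## Problem sizes

Default verification sweeps use m, n ∈ [1, 8] for lattice properties
(the largest built lattice has 800 edges), k = 1..6 for table
reproduction, k = 1..8 for regression and networks, and m = n = 5000 for
the asymptotic entropy check (closed form only — no graph is built). The
whole suite runs in a few seconds.

## Known limitations

* The lattice realization is one of many graphs with the required
  partition; vertex labels and adjacency beyond the contract are not
  meaningful chemically.
* Entropy closed forms skip empty classes (count 0 at m = n = 1), which
  is exact since a zero-count class contributes nothing.
* The similarity measure is scale-sensitive through its Euclidean term:
  variables on very different scales (as the twelve indices are) are
  dominated by distance, which is faithful to the method but worth
  remembering when interpreting clusters.
* Only the twelve rules above are provided — no classical Randić, Wiener
  or first/second Zagreb indices.
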