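# Methods

## Model and definitions

Both input trees are unrooted, with uniquely labelled leaves and internal
nodes of degree ≥ 3 after normalization; branch lengths and internal labels
are ignored. The quartet topology of four leaves is the shape of the minimal
subtree connecting them: one of three butterflies (resolved) or the star
(unresolved, possible only through a node of degree > 3). The quartet
distance is the number of quadruples whose topology differs between the
trees; with fewer than four leaves it is defined as 0.

Butterfly bookkeeping: each tree's resolved quartets split, relative to the
other tree, into identically resolved (shared_B), differently resolved
(diff_B), and star-in-the-other. Summing over both trees and solving gives

    diff_S = B + B′ − 2·shared_B − 2·diff_B,   qdist = diff_S + diff_B,

which the enumeration oracle also verifies directly on every test input.

## Counting machinery

**Claims.** A directed edge e = (s, t) claims the directed quartet ab→cd
when a, b lie in the component of T−t containing s ("behind" e) and c, d lie
in two distinct other components of T−t. Every directed butterfly is claimed
by exactly one directed edge, so summing per-edge-pair counts over ordered
pairs of directed inner edges counts each shared butterfly twice and each
different butterfly four times; the totals must therefore be divisible by 2
and 4, which the code checks at run time (`InternalConsistencyError`
otherwise).

**Intersection table.** Both trees are rooted at their first internal node
in parse order (the result is rooting-invariant; fixing it makes tables
reproducible). A single O(n²) dynamic program fills `D[u, u′] = |down(u) ∩
down(u′)|` over all node pairs: leaf rows are ancestor indicators of the
matching leaf in the other tree, internal rows are child-row sums. Any
component of T−v is a rooted subtree or its complement, so any component
pair's shared-leaf count follows from D by inclusion–exclusion in O(1).

**Per-node-pair aggregates.** For internal v, v′ the matrix
`I[i,j] = |F_i ∩ G_j|` (components ordered by neighbour position, parse
order) is assembled in O(d_v·d_v′), along with row sums R, column sums C,
total M (= n), the elementwise square with its row/column/total sums, the
contractions Σ_k R_k·I[k,j] and Σ_l C_l·I[i,l], Σ R_k², Σ C_l², and matrix
products. Products are computed on the side with the smaller square shape
(ties go left): left = {I·Iᵀ, I′·Iᵀ}, right = {Iᵀ·I, Iᵀ·I′}, plus the triple
product I·Iᵀ·I associated as `(I·Iᵀ)·I` on the left and `I·(Iᵀ·I)` on the
right — the two association orders are the two algebraically equivalent
evaluation paths, and tests assert they agree on every input.

**Closed forms.** With e = I[i,j] and the inner sum

    inner(i,k,j,l) = M − R_i − R_k − C_j − C_l + I[i,j] + I[i,l] + I[k,j] + I[k,l],

the shared count per edge pair is `C(e,2)/2 · Σ_{k≠i,l≠j} I[k,l]·inner(...)`
(the half compensates the (k,l)/(m,n) symmetry; the symmetric sum is provably
even) and the diff count is `e · Σ_{k≠i,l≠j} I[i,l]·I[k,j]·inner(...)`.
Expanding these sums term by term against the stored aggregates collapses
each to an O(1) expression; the only term outside the scalar aggregates is
the diff cross term Σ I[i,l]·I[k,j]·I[k,l] = (I·Iᵀ·I)[i,j] − e·ΣI[i,·]² −
e·ΣI[·,j]² + e³. These rewrites were derived by hand and are enforced by
tests against literal quadruple sums (pure-Python loops, plus a faster
masked-einsum direct sum itself validated against the loops) on thousands of
random matrices — correctness rests on that equivalence, not on transcribed
algebra. In this derivation the shared-count form needs no matrix product;
I′·Iᵀ / Iᵀ·I′ are retained in the table contract and tested, but the final
formulas do not consume them.

**Execution paths.** The same formulas run two ways: a transparent
per-node-pair path over explicit `NodePairTables` (the reference, used for
small inputs and cross-checks) and the production path that groups node
pairs by degree pair and evaluates everything as chunked vectorized array
expressions, including batched matrix products. Tests assert both paths give
identical raw totals; the brute-force oracle then pins both to the
definition.

## Numerical policy

All counts are exact integers. Matrix products go through float64 BLAS only
when a worst-case entry bound (inner dimension × max operand entries) stays
below 2⁵³, where double arithmetic is exact; otherwise they fall back to
native 64-bit integer multiplication, and inputs beyond that raise
`ArithmeticCapacityError`. The batched path additionally guards n ≤ 20 000,
keeping every int64 intermediate (bounded by ~n⁴) below 2⁶³. Per-edge-pair
division by 2 and total divisions by 2 and 4 assert zero remainder.

## Oracle

The O(n⁴) oracle classifies each quadruple by the four-point condition on
unit-edge path lengths (per-leaf BFS): among the three pairing sums
d(a,b)+d(c,d), d(a,c)+d(b,d), d(a,d)+d(b,c), the smallest identifies the
butterfly, and equality of all three identifies the star (the deficit of the
smallest sum is twice the quartet's middle path length, so this is the
path-disjointness definition in distance form). It was chosen over explicit
Steiner-point inspection for being equally definition-level and simpler.

## Synthetic trees

The generators emulate the four benchmark families used to exercise the
degree spectrum; the original families' exact sampling distributions are not
documented, so these are declared replacements, seeded and pure in (n, seed):

* **binary** — iterative uniform random edge subdivision (each new leaf
  splits a uniformly chosen existing edge);
* **general** — a binary tree whose internal edges are independently
  contracted with probability p (default 0.5; p = 0 gives binary, p = 1 the
  star), spanning low to high degrees;
* **star** — one hub of degree n; claims no butterflies;
* **sqrt_hub** — one hub of degree max(3, ⌈√n⌉) (the max keeps the hub a
  genuine multifurcation for n < 9) with leaves split as evenly as possible
  into random binary subtrees.

Synthetic trees are uniformly labelled `t0..t{n−1}` and carry no branch
lengths, label noise, or leaf-set mismatch; tests on them validate the
combinatorial counting exactly, which is the entire claim — the method is
exact, so there is no statistical generalization gap, but the generators say
nothing about the tree shapes real inference methods produce.

## Problem sizes and design choices

* Oracle-equivalence testing uses n ∈ [5, 40] (200+ pairs covering all ten
  family pairings); the oracle is the budget limit, not the method.
* The scaling check times binary pairs at n ∈ {500, 1000, 2000} and requires
  a fitted log–log slope < 3; the acceptance script uses {250, 500, 1000}.
  Slopes observed here are ≈ 1.7 — constant factors (table setup, chunking)
  still shade the asymptotics downward at these sizes, so the slope is
  reported as an empirical observation, not an exponent estimate.
* Leaf-set mismatch and duplicate labels are hard errors; no silent pruning
  to the intersection, so user mistakes surface.
* Rooted Newick inputs are silently unrooted; degree-2 nodes never survive
  normalization, which cannot change any quartet topology (tested via the
  oracle).
* Edge iteration skips edges with a leaf endpoint: a leaf-side behind set
  has C(1,2) = 0 claimable pairs and a leaf target has no two front
  subtrees, so they contribute nothing.

## Limitations

* No branch-length-aware distances, no triplet distance, no batch
  all-pairs mode.
* The O(n^{2+α}) worst-case bound is not asserted empirically; only
  correctness and a soft slope check are.
* Peak memory is O(n²) (the intersection table dominates: one int64 cell per
  node pair), which at the guarded maximum n = 20 000 is the practical
  ceiling.
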