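# quartetdist

Quartet distance between **general** unrooted phylogenetic trees — trees whose
internal nodes may have any degree ≥ 3 — in sub-cubic time, independent of
node degrees.

## The problem

Different inference methods (or different data) for the same *n* species
usually give slightly different trees. The **quartet distance** quantifies the
disagreement: every set of four leaves {a,b,c,d} induces, in each tree, one of
four topologies — three resolved "butterflies" (ab|cd, ac|bd, ad|bc) or, when
the four paths meet at a single high-degree node, the unresolved "star". The
distance is the number of quadruples whose topology differs between the two
trees, at most C(n,4).

Multifurcating trees make this harder than the binary case because star
quartets exist. Writing B and B′ for the butterfly counts of the two trees,
shared_B for quartets resolved identically and diff_B for quartets resolved
differently in both, the star-vs-butterfly disagreements are

    diff_S = B + B′ − 2·shared_B − 2·diff_B

and the distance is `qdist = diff_S + diff_B`. So everything reduces to
counting shared and different butterflies.

## The algorithm

Each butterfly ab|cd orients into two *directed* quartets (ab→cd, ab←cd), and
each directed quartet is *claimed* by exactly one directed edge e: the edge
with a,b behind it and c,d in two distinct subtrees in front. Iterating over
pairs of directed inner edges (e ∈ T, e′ ∈ T′) and counting the directed
butterflies claimed by both counts every shared quartet twice and every
differently-resolved quartet four times.

For the internal node pair (v, v′) targeted by an edge pair, the matrix
`I[i,j] = |F_i ∩ G_j|` of shared leaf counts between the components of T−v and
T′−v′ (available in O(1) per entry from a global O(n²) subtree-intersection
table) turns both per-edge-pair counts into expressions in I. With the row
sums, column sums, elementwise-square aggregates and one triple matrix product
I·Iᵀ·I per node pair, each edge pair is counted in O(1); the matrix products
(done on whichever side is smaller, via BLAS) dominate and keep the total cost
sub-cubic regardless of node degrees. In practice the measured log–log slope
on random binary trees is well below 2 + ω−2 — close to quadratic.

The package also ships a definition-level O(n⁴) enumeration oracle (used to
verify the fast path exactly) and seeded generators for four benchmark
families: random binary, random general (binary + random edge contraction),
star, and √n-hub trees.

## Worked example

```sh
$ qdist gen --n 8 --kind general --seed 11 -o g1.nwk
$ qdist gen --n 8 --kind general --seed 12 -o g2.nwk
$ cat g1.nwk g2.nwk
(t1,t2,(t3,t6),t0,t5,t4,t7);
(t2,t1,t3,(t4,t5,t6),t0,t7);
$ qdist dist g1.nwk g2.nwk --components --normalize
quartet_distance 37
normalized_quartet_distance 0.5285714286
n 8
total_quartets 70
butterflies_tree1 15
butterflies_tree2 30
shared_butterflies 0
different_butterflies 8
star_vs_butterfly 29
```

Of the C(8,4) = 70 quadruples, the first tree resolves 15 and the second 30;
none agree, 8 are resolved differently in both, and 29 are a butterfly in one
tree but a star in the other — 37 differing quartets, 53% of the maximum.
`--method bruteforce` runs the enumeration oracle instead (refused above
n = 1000 without `--force`) and gives identical numbers on every input.

Library use mirrors the CLI:

```python
from quartetdist import parse_newick, quartet_distance
res = quartet_distance(parse_newick("((a,b),(c,d));"),
                       parse_newick("((a,c),(b,d));"))
res.qdist        # 1
res.normalized   # 1.0
```

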