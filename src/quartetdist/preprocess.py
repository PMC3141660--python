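"""Shared-leaf-count tables feeding the quartet counting formulas.

Two layers of precomputation:

1. :class:`IntersectionTable` — an O(n^2) dynamic program over both trees
   rooted at an arbitrary internal node.  ``D[u, u']`` holds the number of
   leaves common to the rooted subtree below ``u`` (in the first tree) and
   below ``u'`` (in the second).  Any component of ``T - v`` is either such a
   rooted subtree or its complement, so the leaf count of any component pair
   follows by inclusion–exclusion in O(1).

2. :class:`NodePairTables` — for one internal node pair ``(v, v')`` with
   component lists ``F_1..F_d`` and ``G_1..G_d'``, the matrix
   ``I[i, j] = |F_i ∩ G_j|`` together with every aggregate the O(1)
   per-edge-pair counting formulas consume: row/column/total sums of ``I``
   and of its elementwise square, the contractions ``Σ_k R_k I[k,j]`` and
   ``Σ_l C_l I[i,l]``, ``Σ R_k²``, ``Σ C_l²``, and the matrix products
   (``I·Iᵀ`` and ``I'·Iᵀ``, or their transposed counterparts, plus the triple
   product ``I·Iᵀ·I``), computed on whichever side has the smaller square
   shape.

All quantities are exact integers.  Matrix products run through float64 BLAS
only while every possible entry stays below 2^53 (exact-double territory);
otherwise they fall back to native integer multiplication, and inputs too
large even for that raise :class:`ArithmeticCapacityError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree_model import DirectedEdge, PhyloTree

__all__ = [
    "IntersectionTable",
    "NodePairTables",
    "ArithmeticCapacityError",
    "build_intersection_table",
    "build_node_pair_tables",
    "choose_product_side",
    "compute_product_aggregates",
]


class ArithmeticCapacityError(OverflowError):
    """Counts would exceed the exact range of the integer backend."""


def _root_structure(tree: PhyloTree):
    """Root at the first internal node (parse order); return parent array,
    a children-before-parent node order, and per-node down-leaf counts."""
    root = tree.internal_nodes[0] if tree.internal_nodes else 0
    n_nodes = len(tree.adj)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    order = []
    stack = [root]
    seen = [False] * n_nodes
    seen[root] = True
    while stack:
        v = stack.pop()
        order.append(v)
        for w in tree.adj[v]:
            if not seen[w]:
                seen[w] = True
                parent[w] = v
                stack.append(w)
    down = np.zeros(n_nodes, dtype=np.int64)
    for v in reversed(order):
        if v in tree.labels:
            down[v] = 1
        if parent[v] >= 0:
            down[parent[v]] += down[v]
    return root, parent, order, down


class IntersectionTable:
    """All ``|F ∩ G|`` counts for subtree pairs across two trees.

    ``D[u, u']`` = number of shared leaves below ``u`` and below ``u'`` in the
    rooted views of the two trees; component/front/behind counts derive from
    it by complement rules.
    """

    def __init__(self, t1: PhyloTree, t2: PhyloTree, leaf_map: dict[str, int]):
        self.t1, self.t2 = t1, t2
        self.leaf_map = leaf_map
        self.n = len(leaf_map)
        self.root1, self.parent1, self.order1, self.down1 = _root_structure(t1)
        self.root2, self.parent2, self.order2, self.down2 = _root_structure(t2)
        self.D = self._build()

    def _build(self) -> np.ndarray:
        t1, t2 = self.t1, self.t2
        n1, n2 = len(t1.adj), len(t2.adj)
        D = np.zeros((n1, n2), dtype=np.int64)
        by_label2 = {lab: v for v, lab in t2.labels.items()}
        # leaf rows: D[u, u'] = 1 iff u' is an ancestor-or-self of u's match
        for u, lab in t1.labels.items():
            w = by_label2[lab]
            while w != -1:
                D[u, w] = 1
                w = self.parent2[w]
        children1: list[list[int]] = [[] for _ in range(n1)]
        for v in range(n1):
            p = self.parent1[v]
            if p >= 0:
                children1[p].append(v)
        for v in reversed(self.order1):
            if children1[v]:
                D[v] = D[children1[v]].sum(axis=0)
        return D

    # -- component descriptors --------------------------------------------

    def component_descriptor(self, which: int, v: int, i: int):
        """Describe component ``i`` of ``T - v`` (the one holding ``adj[v][i]``)
        as ``(key, eps, size)``: the component is ``down(key)`` when ``eps=0``
        and its complement when ``eps=1``; ``size`` is its leaf count."""
        tree = self.t1 if which == 1 else self.t2
        parent = self.parent1 if which == 1 else self.parent2
        down = self.down1 if which == 1 else self.down2
        u = tree.adj[v][i]
        if u == parent[v]:
            return v, 1, self.n - int(down[v])
        return u, 0, int(down[u])

    def _pair_count(self, key1, eps1, key2, eps2) -> int:
        d = int(self.D[key1, key2])
        f = int(self.down1[key1])
        g = int(self.down2[key2])
        if eps1 == 0 and eps2 == 0:
            return d
        if eps1 == 0:
            return f - d
        if eps2 == 0:
            return g - d
        return self.n - f - g + d

    def component_pair_count(self, v1: int, i1: int, v2: int, i2: int) -> int:
        """|F ∩ G| for component i1 of ``T - v1`` vs component i2 of ``T' - v2``."""
        k1, e1, _ = self.component_descriptor(1, v1, i1)
        k2, e2, _ = self.component_descriptor(2, v2, i2)
        return self._pair_count(k1, e1, k2, e2)

    def behind_count(self, which: int, e: DirectedEdge) -> int:
        _, _, size = self.component_descriptor(which, e.target, e.behind_index)
        return size

    def front_count(self, e1: DirectedEdge, e2: DirectedEdge) -> int:
        """Shared-leaf count of the two front sets (leaves on the target side)."""
        k1, e1_, _ = self.component_descriptor(1, e1.target, e1.behind_index)
        k2, e2_, _ = self.component_descriptor(2, e2.target, e2.behind_index)
        # front = complement of the behind component
        return self._pair_count(k1, 1 - e1_, k2, 1 - e2_)

    def node_pair_matrix(self, v1: int, v2: int) -> np.ndarray:
        """The d_v × d_v' matrix ``I`` for an internal node pair."""
        d1 = self.t1.degree(v1)
        d2 = self.t2.degree(v2)
        out = np.empty((d1, d2), dtype=np.int64)
        desc1 = [self.component_descriptor(1, v1, i) for i in range(d1)]
        desc2 = [self.component_descriptor(2, v2, j) for j in range(d2)]
        for i, (k1, e1, _) in enumerate(desc1):
            for j, (k2, e2, _) in enumerate(desc2):
                out[i, j] = self._pair_count(k1, e1, k2, e2)
        return out


def build_intersection_table(
    t1: PhyloTree, t2: PhyloTree, leaf_map: dict[str, int]
) -> IntersectionTable:
    """Build the O(n²) subtree-intersection table for a tree pair."""
    return IntersectionTable(t1, t2, leaf_map)


def choose_product_side(d_v: int, d_vp: int) -> str:
    """Pick the product orientation with the smaller square shape.

    ``"left"`` means {I·Iᵀ, I'·Iᵀ} (d_v × d_v); ``"right"`` means
    {Iᵀ·I, Iᵀ·I'} (d_v' × d_v').  Ties go left.
    """
    return "left" if d_v <= d_vp else "right"


def _exact_matmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact integer matrix product, via BLAS when provably exact in doubles."""
    if a.size == 0 or b.size == 0:
        return np.zeros((a.shape[0], b.shape[1]), dtype=np.int64)
    bound = a.shape[1] * int(a.max(initial=0)) * int(b.max(initial=0))
    if bound < 2**53:
        return np.rint(a.astype(np.float64) @ b.astype(np.float64)).astype(np.int64)
    if bound < 2**63:
        return a.astype(np.int64) @ b.astype(np.int64)
    raise ArithmeticCapacityError(
        f"matrix product entries may reach {bound}, beyond exact 64-bit range"
    )


@dataclass
class NodePairTables:
    """Matrix ``I`` for one internal node pair plus all counting aggregates."""

    I: np.ndarray                 # (d, d') int64, I[i,j] = |F_i ∩ G_j|
    R: np.ndarray                 # row sums
    C: np.ndarray                 # column sums
    M: int                        # total sum (= n when leaf sets coincide)
    I2: np.ndarray                # elementwise square I'
    Rp: np.ndarray                # row sums of I'
    Cp: np.ndarray                # column sums of I'
    SQ: int                       # total of I'
    SR2: int                      # Σ_k R_k²
    SC2: int                      # Σ_l C_l²
    RI_col: np.ndarray            # Σ_k R_k I[k,j], one per column
    CI_row: np.ndarray            # Σ_l C_l I[i,l], one per row
    side: str | None = None       # product orientation actually computed
    gram: np.ndarray | None = None     # I·Iᵀ (left) or Iᵀ·I (right)
    sq_gram: np.ndarray | None = None  # I'·Iᵀ (left) or Iᵀ·I' (right)
    triple: np.ndarray | None = None   # I·Iᵀ·I, shape (d, d')

    @classmethod
    def from_matrix(cls, I: np.ndarray) -> "NodePairTables":
        I = np.asarray(I, dtype=np.int64)
        if I.ndim != 2:
            raise ValueError("I must be a 2-D matrix")
        R = I.sum(axis=1)
        C = I.sum(axis=0)
        I2 = I * I
        return cls(
            I=I,
            R=R,
            C=C,
            M=int(I.sum()),
            I2=I2,
            Rp=I2.sum(axis=1),
            Cp=I2.sum(axis=0),
            SQ=int(I2.sum()),
            SR2=int((R * R).sum()),
            SC2=int((C * C).sum()),
            RI_col=R @ I,
            CI_row=I @ C,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.I.shape


def build_node_pair_tables(v: int, vp: int, table: IntersectionTable) -> NodePairTables:
    """Scalar/vector aggregates for internal nodes ``v ∈ T``, ``vp ∈ T'``."""
    return NodePairTables.from_matrix(table.node_pair_matrix(v, vp))


def compute_product_aggregates(
    tables: NodePairTables, side: str | None = None
) -> NodePairTables:
    """Fill in the matrix products on the chosen (or cheaper) side.

    Both sides produce the same triple product ``I·Iᵀ·I`` — the left path
    associates it as ``(I·Iᵀ)·I``, the right as ``I·(Iᵀ·I)``.
    """
    I, I2 = tables.I, tables.I2
    d, dp = I.shape
    if side is None:
        side = choose_product_side(d, dp)
    elif side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    It = np.ascontiguousarray(I.T)
    if side == "left":
        tables.gram = _exact_matmul(I, It)          # I·Iᵀ
        tables.sq_gram = _exact_matmul(I2, It)      # I'·Iᵀ
        tables.triple = _exact_matmul(tables.gram, I)
    else:
        tables.gram = _exact_matmul(It, I)          # Iᵀ·I
        tables.sq_gram = _exact_matmul(It, I2)      # Iᵀ·I'
        tables.triple = _exact_matmul(I, tables.gram)
    tables.side = side
    return tables
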