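"""Quartet-distance counting over pairs of directed inner edges.

A resolved quartet ab|cd induces two *directed* quartets (ab→cd, ab←cd), and
each directed quartet is claimed by exactly one directed edge: the edge with
a and b behind it and c, d in two distinct subtrees in front.  Summing, over
all pairs of directed inner edges (e ∈ T, e' ∈ T'), the directed butterflies
claimed by both edges counts every shared quartet twice and every
differently-resolved quartet four times.

For an edge pair targeting the internal node pair (v, v') with behind indices
(i, j) in the component matrix I (see ``preprocess``), writing e = I[i,j],
R_i / C_j for row/column sums, M for the total and

    inner(i,k,j,l) = M − R_i − R_k − C_j − C_l
                     + I[i,j] + I[i,l] + I[k,j] + I[k,l]

(the sum of I over rows outside {i,k} and columns outside {j,l}), the raw
per-edge-pair counts are

    shared(i,j) = C(e,2)/2 · Σ_{k≠i, l≠j} I[k,l] · inner(i,k,j,l)
    diff(i,j)   = e · Σ_{k≠i, l≠j} I[i,l] · I[k,j] · inner(i,k,j,l)

Both collapse to O(1) expressions in the precomputed aggregates; the only
term needing a matrix product is the diff cross term, which reads the triple
product (I·Iᵀ·I)[i,j].  The closed forms are verified against literal
quadruple sums in the test suite.

Two execution paths evaluate the same formulas: a transparent per-node-pair
path built on :class:`~quartetdist.preprocess.NodePairTables`, and a batched
production path that groups node pairs by degree pair and evaluates the
formulas as vectorized array expressions.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .preprocess import (
    ArithmeticCapacityError,
    IntersectionTable,
    NodePairTables,
    build_intersection_table,
    build_node_pair_tables,
    compute_product_aggregates,
)
from .tree_model import PhyloTree, shared_leaf_map

__all__ = [
    "DistanceComponents",
    "InternalConsistencyError",
    "inner_sum",
    "shared_directed_for_edge_pair",
    "diff_directed_for_edge_pair",
    "count_shared_butterflies",
    "count_diff_butterflies",
    "butterfly_count",
    "quartet_distance",
]

_MAX_LEAVES = 20_000  # keeps every batched int64 intermediate below 2^63


class InternalConsistencyError(RuntimeError):
    """A count identity that must hold by construction was violated."""


@dataclass(frozen=True)
class DistanceComponents:
    """Exact integer components of the quartet distance.

    ``b1``/``b2``: butterflies (resolved quartets) in each tree;
    ``shared_b``: quartets resolved identically in both; ``diff_b``: resolved
    differently in both; ``diff_s``: star in one tree, butterfly in the
    other; ``qdist = diff_s + diff_b``.
    """

    b1: int
    b2: int
    shared_b: int
    diff_b: int
    diff_s: int
    qdist: int
    n: int

    @property
    def n_quartets(self) -> int:
        return comb(self.n, 4)

    @property
    def normalized(self) -> float:
        """qdist / C(n,4); 0.0 when fewer than 4 leaves."""
        total = self.n_quartets
        return self.qdist / total if total else 0.0

    def validate(self) -> "DistanceComponents":
        if min(self.b1, self.b2, self.shared_b, self.diff_b, self.diff_s, self.qdist) < 0:
            raise InternalConsistencyError(f"negative component in {self}")
        if self.qdist != self.diff_s + self.diff_b:
            raise InternalConsistencyError("qdist != diff_s + diff_b")
        if self.qdist > self.n_quartets:
            raise InternalConsistencyError("qdist exceeds C(n,4)")
        return self


# ---------------------------------------------------------------------------
# O(1) per-edge-pair closed forms (scalar path)
# ---------------------------------------------------------------------------

def inner_sum(tables: NodePairTables, i: int, k: int, j: int, l: int) -> int:
    """Sum of I over rows outside {i, k} and columns outside {j, l}."""
    if i == k or j == l:
        raise ValueError("inner_sum requires i != k and j != l")
    I = tables.I
    return int(
        tables.M
        - tables.R[i] - tables.R[k] - tables.C[j] - tables.C[l]
        + I[i, j] + I[i, l] + I[k, j] + I[k, l]
    )


def _shared_scalar(t: NodePairTables, i: int, j: int) -> int:
    e = int(t.I[i, j])
    if e < 2:
        return 0
    Ri, Cj = int(t.R[i]), int(t.C[j])
    T1 = t.M - Ri - Cj + e
    S = (
        T1 * T1
        - (t.SR2 - Ri * Ri - int(t.RI_col[j]) + Ri * e)
        - (t.SC2 - Cj * Cj - int(t.CI_row[i]) + Cj * e)
        + (int(t.CI_row[i]) - e * Cj - int(t.Rp[i]) + e * e)
        + (int(t.RI_col[j]) - e * Ri - int(t.Cp[j]) + e * e)
        + (t.SQ - int(t.Rp[i]) - int(t.Cp[j]) + e * e)
    )
    if S % 2:
        raise InternalConsistencyError("odd (k,l)/(m,n)-symmetric sum")
    return (e * (e - 1) // 2) * (S // 2)


def _diff_scalar(t: NodePairTables, i: int, j: int) -> int:
    e = int(t.I[i, j])
    if e == 0:
        return 0
    if t.triple is None:
        compute_product_aggregates(t)
    Ri, Cj = int(t.R[i]), int(t.C[j])
    T1 = t.M - Ri - Cj + e
    A = Ri - e
    B = Cj - e
    Rp_i, Cp_j = int(t.Rp[i]), int(t.Cp[j])
    cross = int(t.triple[i, j]) - e * Rp_i - e * Cp_j + e**3
    return e * (
        A * B * T1
        - A * (int(t.RI_col[j]) - Ri * e)
        - B * (int(t.CI_row[i]) - Cj * e)
        + (Rp_i - e * e) * B
        + A * (Cp_j - e * e)
        + cross
    )


def shared_directed_for_edge_pair(tables: NodePairTables, i: int, j: int) -> int:
    """Directed butterflies claimed by both edges (behind indices i, j).

    Already halved for the (k,l)/(m,n) symmetry; an exact integer.
    """
    d, dp = tables.shape
    if not (0 <= i < d and 0 <= j < dp):
        raise IndexError(f"behind index ({i}, {j}) out of range for shape {(d, dp)}")
    return _shared_scalar(tables, i, j)


def diff_directed_for_edge_pair(tables: NodePairTables, i: int, j: int) -> int:
    """Directed-butterfly pairs claimed by both edges with different topology."""
    d, dp = tables.shape
    if not (0 <= i < d and 0 <= j < dp):
        raise IndexError(f"behind index ({i}, {j}) out of range for shape {(d, dp)}")
    return _diff_scalar(tables, i, j)


# ---------------------------------------------------------------------------
# raw totals over all inner-edge pairs
# ---------------------------------------------------------------------------

def _internal_neighbor_indices(tree: PhyloTree, v: int) -> list[int]:
    internal = tree.labels
    return [i for i, u in enumerate(tree.adj[v]) if u not in internal]


def _raw_totals_per_pair(t1: PhyloTree, t2: PhyloTree, table: IntersectionTable):
    """Reference path: explicit NodePairTables per internal node pair."""
    raw_shared = 0
    raw_diff = 0
    nodes1 = [(v, _internal_neighbor_indices(t1, v)) for v in t1.internal_nodes]
    nodes2 = [(vp, _internal_neighbor_indices(t2, vp)) for vp in t2.internal_nodes]
    nodes1 = [x for x in nodes1 if x[1]]
    nodes2 = [x for x in nodes2 if x[1]]
    for v, iis in nodes1:
        for vp, jjs in nodes2:
            tab = build_node_pair_tables(v, vp, table)
            compute_product_aggregates(tab)
            for i in iis:
                for j in jjs:
                    raw_shared += _shared_scalar(tab, i, j)
                    raw_diff += _diff_scalar(tab, i, j)
    return raw_shared, raw_diff


class _NodeGroupPack:
    """Internal nodes of one tree grouped by degree, with per-node component
    descriptors stacked into arrays for batched gathering."""

    def __init__(self, which: int, tree: PhyloTree, table: IntersectionTable):
        parent = table.parent1 if which == 1 else table.parent2
        self.groups: dict[int, dict] = {}
        per_degree: dict[int, list[int]] = {}
        for v in tree.internal_nodes:
            if not _internal_neighbor_indices(tree, v):
                continue  # no inner edge targets this node
            per_degree.setdefault(tree.degree(v), []).append(v)
        for d, vs in per_degree.items():
            key = np.empty((len(vs), d), dtype=np.int64)
            eps = np.empty((len(vs), d), dtype=np.int64)
            inner = np.zeros((len(vs), d), dtype=bool)
            for r, v in enumerate(vs):
                for i, u in enumerate(tree.adj[v]):
                    if u == parent[v]:
                        key[r, i], eps[r, i] = v, 1
                    else:
                        key[r, i], eps[r, i] = u, 0
                    inner[r, i] = u not in tree.labels
            self.groups[d] = {"key": key, "eps": eps, "inner": inner}


def _batched_products(I: np.ndarray, d: int, dp: int) -> np.ndarray:
    """Triple product I·Iᵀ·I per stacked matrix, associated on the smaller side."""
    If = I.astype(np.float64)
    if d <= dp:
        J = (If @ If.transpose(0, 2, 1)) @ If
    else:
        J = If @ (If.transpose(0, 2, 1) @ If)
    return np.rint(J).astype(np.int64)


def _raw_totals_batched(t1: PhyloTree, t2: PhyloTree, table: IntersectionTable):
    """Production path: identical formulas, vectorized over node pairs."""
    n = table.n
    if n > _MAX_LEAVES:
        raise ArithmeticCapacityError(f"n={n} exceeds exact-arithmetic guard {_MAX_LEAVES}")
    pack1 = _NodeGroupPack(1, t1, table)
    pack2 = _NodeGroupPack(2, t2, table)
    D = table.D
    down1, down2 = table.down1, table.down2
    raw_shared = 0
    raw_diff = 0
    target_elems = 1 << 20
    for d, g1 in pack1.groups.items():
        for dp, g2 in pack2.groups.items():
            m1 = g1["key"].shape[0]
            m2 = g2["key"].shape[0]
            chunk = max(1, target_elems // (d * dp))
            pairs = m1 * m2
            for start in range(0, pairs, chunk):
                idx = np.arange(start, min(start + chunk, pairs))
                a, b = idx // m2, idx % m2
                K1 = g1["key"][a]            # (B, d)
                K2 = g2["key"][b]            # (B, dp)
                E1 = g1["eps"][a][:, :, None]
                E2 = g2["eps"][b][:, None, :]
                Dsub = D[K1[:, :, None], K2[:, None, :]]
                fsz = down1[K1][:, :, None]
                gsz = down2[K2][:, None, :]
                I = (
                    (1 - E1) * (1 - E2) * Dsub
                    + (1 - E1) * E2 * (fsz - Dsub)
                    + E1 * (1 - E2) * (gsz - Dsub)
                    + E1 * E2 * (n - fsz - gsz + Dsub)
                )
                R = I.sum(axis=2)            # (B, d)
                C = I.sum(axis=1)            # (B, dp)
                I2 = I * I
                Rp = I2.sum(axis=2)
                Cp = I2.sum(axis=1)
                SQ = I2.sum(axis=(1, 2))[:, None, None]
                SR2 = (R * R).sum(axis=1)[:, None, None]
                SC2 = (C * C).sum(axis=1)[:, None, None]
                RIc = np.einsum("bk,bkj->bj", R, I)[:, None, :]
                CIr = np.einsum("bil,bl->bi", I, C)[:, :, None]
                J = _batched_products(I, d, dp)
                Rb = R[:, :, None]
                Cb = C[:, None, :]
                Rpb = Rp[:, :, None]
                Cpb = Cp[:, None, :]
                T1 = n - Rb - Cb + I
                S = (
                    T1 * T1
                    - (SR2 - Rb * Rb - RIc + Rb * I)
                    - (SC2 - Cb * Cb - CIr + Cb * I)
                    + (CIr - I * Cb - Rpb + I2)
                    + (RIc - I * Rb - Cpb + I2)
                    + (SQ - Rpb - Cpb + I2)
                )
                mask = g1["inner"][a][:, :, None] & g2["inner"][b][:, None, :]
                if (S[mask] & 1).any():
                    raise InternalConsistencyError("odd (k,l)/(m,n)-symmetric sum")
                sh = (I * (I - 1) // 2) * (S >> 1)
                A = Rb - I
                Bv = Cb - I
                df = I * (
                    A * Bv * T1
                    - A * (RIc - Rb * I)
                    - Bv * (CIr - Cb * I)
                    + (Rpb - I2) * Bv
                    + A * (Cpb - I2)
                    + (J - I * Rpb - I * Cpb + I2 * I)
                )
                raw_shared += int(sh[mask].sum())
                raw_diff += int(df[mask].sum())
    return raw_shared, raw_diff


def _raw_totals(t1, t2, table=None, method="batched"):
    if table is None:
        table = build_intersection_table(t1, t2, shared_leaf_map(t1, t2))
    if method == "batched":
        return _raw_totals_batched(t1, t2, table)
    if method == "per_pair":
        return _raw_totals_per_pair(t1, t2, table)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# public counts
# ---------------------------------------------------------------------------

def count_shared_butterflies(t1: PhyloTree, t2: PhyloTree, method: str = "batched") -> int:
    """Quartets with the same butterfly topology in both trees."""
    shared_leaf_map(t1, t2)
    raw, _ = _raw_totals(t1, t2, method=method)
    if raw % 2:
        raise InternalConsistencyError(f"raw shared total {raw} is odd")
    return raw // 2


def count_diff_butterflies(t1: PhyloTree, t2: PhyloTree, method: str = "batched") -> int:
    """Quartets resolved as different butterflies in the two trees."""
    shared_leaf_map(t1, t2)
    _, raw = _raw_totals(t1, t2, method=method)
    if raw % 4:
        raise InternalConsistencyError(f"raw diff total {raw} not divisible by 4")
    return raw // 4


def butterfly_count(t: PhyloTree, method: str = "batched") -> int:
    """Number of resolved (butterfly) quartets in one tree:
    shared count of the tree against itself."""
    return count_shared_butterflies(t, t, method=method)


def quartet_distance(
    t1: PhyloTree, t2: PhyloTree, method: str = "batched"
) -> DistanceComponents:
    """Full quartet-distance decomposition between two trees.

    Each tree's butterflies split into shared, differently-resolved, and
    star-in-the-other quartets, so

        diff_s = B + B' − 2·shared_b − 2·diff_b
        qdist  = diff_s + diff_b
    """
    leaf_map = shared_leaf_map(t1, t2)
    n = len(leaf_map)
    if n < 4:
        return DistanceComponents(0, 0, 0, 0, 0, 0, n)
    table = build_intersection_table(t1, t2, leaf_map)
    raw_sh, raw_df = _raw_totals(t1, t2, table, method)
    if raw_sh % 2 or raw_df % 4:
        raise InternalConsistencyError(
            f"raw totals ({raw_sh}, {raw_df}) violate 2/4 divisibility"
        )
    shared_b = raw_sh // 2
    diff_b = raw_df // 4
    b1 = count_shared_butterflies(t1, t1, method=method)
    b2 = count_shared_butterflies(t2, t2, method=method)
    diff_s = b1 + b2 - 2 * shared_b - 2 * diff_b
    qdist = diff_s + diff_b
    return DistanceComponents(b1, b2, shared_b, diff_b, diff_s, qdist, n).validate()
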