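"""Definition-level O(n^4) quartet enumeration, used as ground truth.

The quartet topology of four leaves {a,b,c,d} is read off the four-point
condition on unit-length path distances: among the three pairing sums
d(a,b)+d(c,d), d(a,c)+d(b,d), d(a,d)+d(b,c) the two largest are always equal;
the topology is the pairing with the strictly smallest sum, and the quartet
is a star iff all three sums are equal.  This is equivalent to the
path-disjointness definition (the deficit of the smallest sum is twice the
length of the quartet's middle path) and is simple enough to trust.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations

import numpy as np

from .counting import DistanceComponents
from .tree_model import PhyloTree, shared_leaf_map

__all__ = ["STAR", "quartet_topology", "brute_force_components"]

STAR = 0  # topology codes: 0 star, 1 ab|cd, 2 ac|bd, 3 ad|bc (sorted quadruple)


def _leaf_distance_matrix(tree: PhyloTree, leaf_map: dict[str, int]) -> np.ndarray:
    """All-pairs unit-edge path lengths between leaves, BFS per leaf."""
    n = len(leaf_map)
    n_nodes = len(tree.adj)
    out = np.zeros((n, n), dtype=np.int64)
    node_of = {leaf_map[lab]: v for v, lab in tree.labels.items()}
    for i in range(n):
        src = node_of[i]
        dist = np.full(n_nodes, -1, dtype=np.int64)
        dist[src] = 0
        q = deque([src])
        while q:
            v = q.popleft()
            for w in tree.adj[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    q.append(w)
        for j in range(n):
            out[i, j] = dist[node_of[j]]
    return out


def _topology_codes(dm: np.ndarray, quads: np.ndarray) -> np.ndarray:
    """Topology code per quadruple (rows of ``quads`` sorted ascending)."""
    a, b, c, d = quads[:, 0], quads[:, 1], quads[:, 2], quads[:, 3]
    s1 = dm[a, b] + dm[c, d]  # ab|cd
    s2 = dm[a, c] + dm[b, d]  # ac|bd
    s3 = dm[a, d] + dm[b, c]  # ad|bc
    sums = np.stack([s1, s2, s3], axis=1)
    lo = sums.min(axis=1)
    n_min = (sums == lo[:, None]).sum(axis=1)
    codes = sums.argmin(axis=1) + 1
    codes[n_min == 3] = STAR
    return codes


def quartet_topology(tree: PhyloTree, quad: tuple[int, int, int, int],
                     leaf_map: dict[str, int] | None = None) -> int:
    """Topology code for one quadruple of leaf indices.

    Returns ``STAR`` (0) or 1/2/3 for ab|cd, ac|bd, ad|bc relative to the
    sorted quadruple.
    """
    if len(set(quad)) != 4:
        raise ValueError(f"quartet requires 4 distinct leaves, got {quad}")
    if leaf_map is None:
        leaf_map = {lab: i for i, lab in enumerate(sorted(tree.leaf_set()))}
    if any(not 0 <= q < len(leaf_map) for q in quad):
        raise ValueError(f"leaf index out of range in {quad}")
    dm = _leaf_distance_matrix(tree, leaf_map)
    quads = np.array([sorted(quad)])
    return int(_topology_codes(dm, quads)[0])


def brute_force_components(t1: PhyloTree, t2: PhyloTree) -> DistanceComponents:
    """Tally every C(n,4) quadruple's topology in both trees."""
    leaf_map = shared_leaf_map(t1, t2)
    n = len(leaf_map)
    if n < 4:
        return DistanceComponents(0, 0, 0, 0, 0, 0, n)
    dm1 = _leaf_distance_matrix(t1, leaf_map)
    dm2 = _leaf_distance_matrix(t2, leaf_map)
    quads = np.fromiter(
        (i for quad in combinations(range(n), 4) for i in quad), dtype=np.int64
    ).reshape(-1, 4)
    c1 = _topology_codes(dm1, quads)
    c2 = _topology_codes(dm2, quads)
    r1 = c1 != STAR
    r2 = c2 != STAR
    b1 = int(r1.sum())
    b2 = int(r2.sum())
    shared_b = int((r1 & r2 & (c1 == c2)).sum())
    diff_b = int((r1 & r2 & (c1 != c2)).sum())
    diff_s = int((r1 != r2).sum())
    qdist = int((c1 != c2).sum())
    return DistanceComponents(b1, b2, shared_b, diff_b, diff_s, qdist, n).validate()
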