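"""Seeded generators for the four benchmark tree families.

* ``binary``  — random binary tree by sequential attachment to a uniformly
  random edge (each leaf added splits an existing edge);
* ``general`` — a random binary tree with every internal edge independently
  contracted with probability ``contraction_p`` (default 0.5), spanning the
  degree spectrum between binary (p=0) and star (p=1);
* ``star``    — one hub of degree n;
* ``sqrt_hub`` — one hub of degree max(3, ceil(sqrt(n))) whose neighbouring
  subtrees are random binary trees over an (as even as possible) partition
  of the leaves.

All generators are pure functions of (n, seed): the same arguments always
yield the identical tree.  Leaves are labelled ``t0..t{n-1}``.
"""

from __future__ import annotations

import math

import numpy as np

from .tree_model import PhyloTree

__all__ = [
    "KINDS",
    "random_binary_tree",
    "random_general_tree",
    "star_tree",
    "sqrt_hub_tree",
    "generate",
]

KINDS = ("general", "binary", "star", "sqrt_hub")


def _labels(n: int, offset: int = 0) -> list[str]:
    return [f"t{i}" for i in range(offset, offset + n)]


def _binary_adjacency(leaf_names: list[str], rng: np.random.Generator):
    """Random binary topology over given leaves, as (adj, labels) with fresh ids."""
    n = len(leaf_names)
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    labels = {i: leaf_names[i] for i in range(n)}
    next_id = n
    if n == 1:
        return adj, labels
    edges = [(0, 1)]
    adj[0].append(1)
    adj[1].append(0)
    for leaf in range(2, n):
        eidx = int(rng.integers(len(edges)))
        u, w = edges[eidx]
        x = next_id
        next_id += 1
        adj[x] = [u, w, leaf]
        adj[u][adj[u].index(w)] = x
        adj[w][adj[w].index(u)] = x
        adj[leaf] = [x]
        edges[eidx] = (u, x)
        edges.append((x, w))
        edges.append((x, leaf))
    return adj, labels


def random_binary_tree(n: int, seed: int) -> PhyloTree:
    """Unrooted random binary tree: every internal node has degree 3."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    adj, labels = _binary_adjacency(_labels(n), rng)
    return PhyloTree.from_adjacency(adj, labels)


def random_general_tree(n: int, seed: int, contraction_p: float = 0.5) -> PhyloTree:
    """Random multifurcating tree: binary skeleton + i.i.d. edge contraction."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= contraction_p <= 1.0:
        raise ValueError("contraction_p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    adj, labels = _binary_adjacency(_labels(n), rng)
    internal_edges = sorted(
        (u, w) for u, nbrs in adj.items() for w in nbrs
        if u < w and u not in labels and w not in labels
    )
    # union-find merge of contracted edges
    root_of = {v: v for v in adj}

    def find(v):
        while root_of[v] != v:
            root_of[v] = root_of[root_of[v]]
            v = root_of[v]
        return v

    for (u, w) in internal_edges:
        if rng.random() < contraction_p:
            root_of[find(w)] = find(u)
    merged: dict[int, list[int]] = {}
    for u, nbrs in adj.items():
        ru = find(u)
        merged.setdefault(ru, [])
        for w in nbrs:
            rw = find(w)
            if rw != ru:
                merged[ru].append(rw)
    return PhyloTree.from_adjacency(merged, {find(v): lab for v, lab in labels.items()})


def star_tree(n: int) -> PhyloTree:
    """All n leaves attached to one hub (for n >= 3)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    labels = {i: f"t{i}" for i in range(n)}
    if n == 1:
        return PhyloTree.from_adjacency({0: []}, labels)
    if n == 2:
        return PhyloTree.from_adjacency({0: [1], 1: [0]}, labels)
    hub = n
    adj = {i: [hub] for i in range(n)}
    adj[hub] = list(range(n))
    return PhyloTree.from_adjacency(adj, labels)


def sqrt_hub_tree(n: int, seed: int) -> PhyloTree:
    """Hub of degree max(3, ceil(sqrt(n))) with random binary subtrees.

    The n leaves are split across the hub's subtrees as evenly as possible;
    every non-hub internal node has degree 3.
    """
    if n < 4:
        raise ValueError("sqrt_hub_tree requires n >= 4")
    rng = np.random.default_rng(seed)
    h = max(3, math.ceil(math.sqrt(n)))
    base, extra = divmod(n, h)
    sizes = [base + (1 if g < extra else 0) for g in range(h)]
    adj: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    hub = 0
    adj[hub] = []
    next_id = 1
    offset = 0
    for size in sizes:
        sub_adj, sub_labels = _binary_adjacency(_labels(size, offset), rng)
        offset += size
        remap = {v: next_id + v for v in sub_adj}
        next_id += len(sub_adj)
        for v, nbrs in sub_adj.items():
            adj[remap[v]] = [remap[w] for w in nbrs]
        for v, lab in sub_labels.items():
            labels[remap[v]] = lab
        if size == 1:
            anchor = remap[0]
        else:
            # subdivide a uniformly random edge with the attachment point
            edges = sorted(
                (a, b) for a, nb in sub_adj.items() for b in nb if a < b
            )
            a, b = edges[int(rng.integers(len(edges)))]
            a, b = remap[a], remap[b]
            anchor = next_id
            next_id += 1
            adj[a][adj[a].index(b)] = anchor
            adj[b][adj[b].index(a)] = anchor
            adj[anchor] = [a, b]
        adj[anchor].append(hub)
        adj[hub].append(anchor)
    return PhyloTree.from_adjacency(adj, labels)


def generate(kind: str, n: int, seed: int = 0, contraction_p: float = 0.5) -> PhyloTree:
    """Dispatch on the benchmark family name."""
    if kind == "binary":
        return random_binary_tree(n, seed)
    if kind == "general":
        return random_general_tree(n, seed, contraction_p)
    if kind == "star":
        return star_tree(n)
    if kind == "sqrt_hub":
        return sqrt_hub_tree(n, seed)
    raise ValueError(f"unknown tree kind {kind!r}; expected one of {KINDS}")
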