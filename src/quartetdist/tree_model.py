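"""Unrooted multifurcating phylogenetic trees with a shared leaf index space.

Trees are stored as plain adjacency lists over integer node ids.  Parsing goes
through dendropy's Newick reader; everything but the topology and the leaf
labels (branch lengths, internal labels, rooting) is discarded, because the
quartet distance depends on the topology alone.  After normalization every
surviving internal node has degree >= 3: degree-2 nodes — including the
artificial "root" of a rooted input — are suppressed.

Node numbering and neighbour ordering are deterministic functions of the input
text (left-to-right parse order).  The counting machinery indexes the
components of ``T - v`` by position in ``adj[v]``, so this ordering is part of
the module contract, not a cosmetic detail.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "PhyloTree",
    "DirectedEdge",
    "NewickParseError",
    "TreeValidationError",
    "LeafSetMismatchError",
    "parse_newick",
    "write_newick",
    "shared_leaf_map",
]


class NewickParseError(ValueError):
    """Malformed Newick input (message carries dendropy's position info)."""


class TreeValidationError(ValueError):
    """Structurally valid parse but an invalid tree (duplicate/empty labels, no leaves)."""


class LeafSetMismatchError(ValueError):
    """The two trees do not share an identical leaf-label set."""

    def __init__(self, only_first: set[str], only_second: set[str]):
        self.only_first = frozenset(only_first)
        self.only_second = frozenset(only_second)
        super().__init__(
            "leaf sets differ: only in first tree %s; only in second tree %s"
            % (sorted(only_first), sorted(only_second))
        )


@dataclass(frozen=True)
class DirectedEdge:
    """An oriented edge ``source -> target``.

    ``behind_index`` is the position of ``source`` in ``adj[target]``: it
    selects the component of ``T - target`` that lies *behind* the edge,
    i.e. the subtree whose leaf pairs the edge can claim.
    """

    source: int
    target: int
    behind_index: int


class PhyloTree:
    """Normalized unrooted tree: adjacency lists plus leaf labels.

    Invariants (enforced at construction):

    * connected and acyclic;
    * every unlabeled (internal) node has degree >= 3;
    * leaf labels are unique non-empty strings;
    * node ids are ``0..len(adj)-1``.
    """

    __slots__ = ("adj", "labels", "_leaves", "_internal")

    def __init__(self, adj: list[list[int]], labels: dict[int, str]):
        self.adj = adj
        self.labels = labels
        self._leaves = sorted(labels)
        self._internal = [v for v in range(len(adj)) if v not in labels]
        self._validate()

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        """Number of leaves."""
        return len(self.labels)

    @property
    def leaves(self) -> list[int]:
        return self._leaves

    @property
    def internal_nodes(self) -> list[int]:
        return self._internal

    def degree(self, v: int) -> int:
        return len(self.adj[v])

    def leaf_set(self) -> set[str]:
        return set(self.labels.values())

    def edges(self):
        """Undirected edges as (u, v) with u < v."""
        for u, nbrs in enumerate(self.adj):
            for v in nbrs:
                if u < v:
                    yield (u, v)

    def directed_inner_edges(self):
        """All ``DirectedEdge``s with both endpoints internal (both orientations)."""
        internal = set(self._internal)
        for t in self._internal:
            for i, s in enumerate(self.adj[t]):
                if s in internal:
                    yield DirectedEdge(s, t, i)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_adjacency(cls, adj: dict[int, list[int]], labels: dict[int, str]) -> "PhyloTree":
        """Build from a raw adjacency map, normalizing and renumbering.

        Suppresses unlabeled nodes of degree <= 2 and renumbers nodes
        compactly by a DFS in neighbour order from the lowest surviving id.
        """
        adj = {v: list(nb) for v, nb in adj.items()}
        changed = True
        while changed:
            changed = False
            for v in sorted(adj):
                if v in labels:
                    continue
                deg = len(adj[v])
                if deg == 2:
                    a, b = adj[v]
                    adj[a][adj[a].index(v)] = b
                    adj[b][adj[b].index(v)] = a
                    del adj[v]
                    changed = True
                elif deg == 1:
                    (a,) = adj[v]
                    adj[a].remove(v)
                    del adj[v]
                    changed = True
                elif deg == 0 and len(adj) > 1:
                    del adj[v]
                    changed = True
        if not adj:
            raise TreeValidationError("tree has no leaves")
        # compact renumbering, preserving neighbour order
        order: list[int] = []
        seen: set[int] = set()
        stack = [min(adj)]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            order.append(v)
            stack.extend(reversed(adj[v]))
        if len(order) != len(adj):
            raise TreeValidationError("tree is not connected")
        new_id = {v: i for i, v in enumerate(order)}
        new_adj = [[new_id[w] for w in adj[v]] for v in order]
        new_labels = {new_id[v]: lab for v, lab in labels.items() if v in new_id}
        return cls(new_adj, new_labels)

    def _validate(self) -> None:
        if not self.labels:
            raise TreeValidationError("tree has no leaves")
        labs = list(self.labels.values())
        if any(not isinstance(l, str) or l == "" for l in labs):
            raise TreeValidationError("empty or non-string leaf label")
        if len(set(labs)) != len(labs):
            dups = sorted({l for l in labs if labs.count(l) > 1})
            raise TreeValidationError(f"duplicate leaf labels: {dups}")
        n_nodes = len(self.adj)
        n_edges = sum(len(nb) for nb in self.adj) // 2
        if n_nodes > 1 and n_edges != n_nodes - 1:
            raise TreeValidationError("not a tree: edges != nodes - 1")
        for v in self._internal:
            if len(self.adj[v]) < 3:
                raise TreeValidationError(f"internal node {v} has degree {len(self.adj[v])} < 3")

    # -- structural comparison --------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Edge-induced leaf bipartitions, each as the lexicographically
        smaller side.  Two trees on the same leaf set are isomorphic iff
        their bipartition sets coincide."""
        full = frozenset(self.labels.values())
        out: set[frozenset[str]] = set()
        for u, v in self.edges():
            side = frozenset(self._leaves_beyond(u, v))
            other = full - side
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out

    def _leaves_beyond(self, u: int, v: int) -> list[str]:
        """Leaf labels in the component of ``T - u`` containing ``v``."""
        out = []
        stack = [(v, u)]
        while stack:
            node, parent = stack.pop()
            if node in self.labels:
                out.append(self.labels[node])
            for w in self.adj[node]:
                if w != parent:
                    stack.append((w, node))
        return out

    def is_isomorphic(self, other: "PhyloTree") -> bool:
        return (
            self.leaf_set() == other.leaf_set()
            and self.bipartitions() == other.bipartitions()
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n={self.n}, nodes={len(self.adj)})"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a normalized :class:`PhyloTree`.

    Branch lengths, internal node labels and comments are accepted and
    discarded.  A rooted input (top-level bifurcation) is silently unrooted.
    Raises :class:`NewickParseError` on bad syntax (with position) and
    :class:`TreeValidationError` on duplicate/empty labels or an empty tree.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        msg = str(exc)
        if "Multiple occurrences of the same taxa" in msg:
            raise TreeValidationError(f"duplicate leaf label: {msg}") from exc
        raise NewickParseError(msg) from exc

    adj: dict[int, list[int]] = {}
    labels: dict[int, str] = {}
    ids: dict[int, int] = {}
    for i, nd in enumerate(dtree.preorder_node_iter()):
        ids[id(nd)] = i
        adj[i] = []
    for nd in dtree.preorder_node_iter():
        v = ids[id(nd)]
        if nd.is_leaf():
            if nd.taxon is None or not (nd.taxon.label or "").strip():
                raise TreeValidationError("leaf with empty label")
            labels[v] = nd.taxon.label
        for ch in nd.child_nodes():
            w = ids[id(ch)]
            adj[v].append(w)
            adj[w].insert(0, v)  # parent first, then children in parse order
    return PhyloTree.from_adjacency(adj, labels)


_PLAIN_LABEL = re.compile(r"^[^\s()\[\]{}:;,\"']+$")


def _fmt_label(label: str) -> str:
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick (topology and leaf labels only, trailing ';').

    ``parse_newick(write_newick(t))`` is isomorphic to ``t``.
    """
    if len(tree.adj) == 1:
        return _fmt_label(tree.labels[0]) + ";"

    def sub(v: int, parent: int) -> str:
        if v in tree.labels:
            return _fmt_label(tree.labels[v])
        parts = [sub(w, v) for w in tree.adj[v] if w != parent]
        return "(" + ",".join(parts) + ")"

    if tree.internal_nodes:
        root = tree.internal_nodes[0]
        return "(" + ",".join(sub(w, root) for w in tree.adj[root]) + ");"
    # two leaves joined by an edge
    a, b = 0, tree.adj[0][0]
    return f"({_fmt_label(tree.labels[a])},{_fmt_label(tree.labels[b])});"


def shared_leaf_map(t1: PhyloTree, t2: PhyloTree) -> dict[str, int]:
    """Common ``label -> index`` map for two trees on the same leaf set.

    Indices are assigned in sorted label order; both trees address leaves
    through the same table.  Raises :class:`LeafSetMismatchError` naming the
    symmetric difference if the leaf sets differ.
    """
    s1, s2 = t1.leaf_set(), t2.leaf_set()
    if s1 != s2:
        raise LeafSetMismatchError(s1 - s2, s2 - s1)
    return {lab: i for i, lab in enumerate(sorted(s1))}
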