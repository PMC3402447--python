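"""Unrooted leaf-labelled trees: Newick I/O, comparison, path-length matrices.

Trees are stored as undirected adjacency maps with per-edge optional branch
lengths (non-negative reals) and optional integer bootstrap supports in
[0, 100].  All downstream analyses treat trees as unrooted: a degree-2 root
in the input is suppressed on load, and bipartitions are properties of
internal edges.

Newick conventions follow the output of common ML programs: bootstrap
supports appear as internal-node labels, branch lengths after ``:``.
Serialization is canonical (children ordered by their lexicographically
smallest descendant leaf) so that equal trees produce byte-identical text.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import dendropy

from .distmat import DistanceMatrix

__all__ = [
    "Tree",
    "Edge",
    "TreeError",
    "NewickError",
    "ValidationError",
    "parse_newick",
    "write_newick",
    "read_newick_trees",
    "write_newick_trees",
    "robinson_foulds",
    "path_length_matrix",
]


class TreeError(ValueError):
    """Base class for tree-related errors."""


class NewickError(TreeError):
    """Malformed Newick input."""


class ValidationError(TreeError):
    """Structurally invalid tree or inconsistent arguments."""


_NEWICK_META = set("();:,'[]\t\n ")


@dataclass
class Edge:
    """Undirected edge payload: optional length and optional support."""

    length: float | None = None
    support: int | None = None

    def copy(self) -> "Edge":
        return Edge(self.length, self.support)


class Tree:
    """Unrooted leaf-labelled tree over an undirected adjacency map.

    Nodes are opaque integers; leaves carry unique text labels.  Internal
    nodes may have any degree >= 3 (polytomies are allowed), so star trees
    parse and serialize fine even though most algorithms downstream require
    binary trees.
    """

    __slots__ = ("_adj", "_label", "_node_of", "_next")

    def __init__(self) -> None:
        self._adj: dict[int, dict[int, Edge]] = {}
        self._label: dict[int, str] = {}
        self._node_of: dict[str, int] = {}
        self._next = 0

    # -- construction ------------------------------------------------------

    def add_node(self, label: str | None = None) -> int:
        v = self._next
        self._next += 1
        self._adj[v] = {}
        if label is not None:
            if not label:
                raise ValidationError("empty taxon label")
            if label in self._node_of:
                raise ValidationError(f"duplicate leaf label: {label!r}")
            self._label[v] = label
            self._node_of[label] = v
        return v

    def add_edge(
        self, u: int, v: int, length: float | None = None, support: int | None = None
    ) -> Edge:
        if u == v or v in self._adj[u]:
            raise ValidationError(f"bad edge ({u},{v})")
        if length is not None and (not math.isfinite(length) or length < 0):
            raise ValidationError(f"branch length must be finite and >= 0, got {length}")
        if support is not None and not (0 <= support <= 100):
            raise ValidationError(f"support must be in [0,100], got {support}")
        e = Edge(length, support)
        self._adj[u][v] = e
        self._adj[v][u] = e
        return e

    def remove_edge(self, u: int, v: int) -> None:
        del self._adj[u][v]
        del self._adj[v][u]

    def remove_node(self, v: int) -> None:
        for w in list(self._adj[v]):
            self.remove_edge(v, w)
        del self._adj[v]
        lab = self._label.pop(v, None)
        if lab is not None:
            del self._node_of[lab]

    def copy(self) -> "Tree":
        t = Tree.__new__(Tree)
        t._adj = {}
        t._label = dict(self._label)
        t._node_of = dict(self._node_of)
        t._next = self._next
        seen: dict[tuple[int, int], Edge] = {}
        for u, nbrs in self._adj.items():
            t._adj[u] = {}
        for u, nbrs in self._adj.items():
            for v, e in nbrs.items():
                key = (min(u, v), max(u, v))
                if key not in seen:
                    seen[key] = e.copy()
                t._adj[u][v] = seen[key]
        return t

    # -- interrogation -----------------------------------------------------

    @property
    def nodes(self) -> Iterable[int]:
        return self._adj.keys()

    def neighbors(self, v: int) -> Iterable[int]:
        return self._adj[v].keys()

    def degree(self, v: int) -> int:
        return len(self._adj[v])

    def is_leaf(self, v: int) -> bool:
        return v in self._label

    def label(self, v: int) -> str:
        return self._label[v]

    def node_of(self, label: str) -> int:
        return self._node_of[label]

    def leaves(self) -> list[int]:
        return sorted(self._label, key=self._label.__getitem__)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(self._node_of))

    @property
    def n_leaves(self) -> int:
        return len(self._label)

    def edge(self, u: int, v: int) -> Edge:
        return self._adj[u][v]

    def edges(self) -> Iterator[tuple[int, int, Edge]]:
        for u, nbrs in self._adj.items():
            for v, e in nbrs.items():
                if u < v:
                    yield u, v, e

    def internal_edges(self) -> Iterator[tuple[int, int, Edge]]:
        """Edges whose removal yields a non-trivial bipartition."""
        for u, v, e in self.edges():
            if not self.is_leaf(u) and not self.is_leaf(v):
                yield u, v, e

    def is_binary(self) -> bool:
        return all(
            self.degree(v) == 3 for v in self._adj if not self.is_leaf(v)
        ) and all(self.degree(v) == 1 for v in self._label)

    # -- bipartitions ------------------------------------------------------

    def side_labels(self, u: int, v: int) -> frozenset[str]:
        """Leaf labels on the ``v`` side of edge (u, v)."""
        stack, seen, out = [v], {u, v}, []
        while stack:
            w = stack.pop()
            if self.is_leaf(w):
                out.append(self._label[w])
            for x in self._adj[w]:
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        return frozenset(out)

    def bipartition_set(self) -> frozenset[frozenset[str]]:
        """Canonical non-trivial bipartitions (side holding the smallest taxon)."""
        if not self._node_of:
            return frozenset()
        smallest = min(self._node_of)
        all_taxa = frozenset(self._node_of)
        out = set()
        for u, v, _ in self.internal_edges():
            side = self.side_labels(u, v)
            if smallest not in side:
                side = all_taxa - side
            if 1 < len(side) < len(all_taxa) - 1 or (
                len(side) >= 2 and len(all_taxa - side) >= 2
            ):
                out.add(side)
        return frozenset(out)

    # -- structural edits --------------------------------------------------

    def suppress_unlabelled_low_degree(self) -> None:
        """Remove unlabelled degree-0/1 nodes; splice out degree-2 ones.

        Splicing sums branch lengths and keeps the larger support of the two
        merged edges (they describe the same unrooted edge).
        """
        changed = True
        while changed:
            changed = False
            for v in list(self._adj):
                if v in self._label or v not in self._adj:
                    continue
                deg = self.degree(v)
                if deg <= 1:
                    self.remove_node(v)
                    changed = True
                elif deg == 2:
                    (a, ea), (b, eb) = self._adj[v].items()
                    length: float | None
                    if ea.length is None and eb.length is None:
                        length = None
                    else:
                        length = (ea.length or 0.0) + (eb.length or 0.0)
                    sups = [s for s in (ea.support, eb.support) if s is not None]
                    support = max(sups) if sups else None
                    self.remove_node(v)
                    if b not in self._adj[a]:
                        self.add_edge(a, b, length, support)
                    changed = True

    def restrict(self, taxa: Iterable[str]) -> "Tree":
        """Prune to a taxon subset, suppressing resulting degree-2 nodes."""
        keep = set(taxa)
        missing = keep - set(self._node_of)
        if missing:
            raise ValidationError(f"taxa not in tree: {sorted(missing)}")
        t = self.copy()
        for lab in list(t._node_of):
            if lab not in keep:
                t.remove_node(t._node_of[lab])
        t.suppress_unlabelled_low_degree()
        return t

    def validate(self) -> None:
        if not self._adj:
            raise ValidationError("empty tree")
        # connectivity
        start = next(iter(self._adj))
        seen = {start}
        stack = [start]
        while stack:
            w = stack.pop()
            for x in self._adj[w]:
                if x not in seen:
                    seen.add(x)
                    stack.append(x)
        if len(seen) != len(self._adj):
            raise ValidationError("tree is not connected")
        for v in self._label:
            if self.degree(v) != 1 and len(self._adj) > 1:
                raise ValidationError(f"leaf {self._label[v]!r} has degree != 1")


# -- Newick I/O ------------------------------------------------------------


def _quote_label(label: str) -> str:
    if any(c in _NEWICK_META for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_length(x: float) -> str:
    return f"{x:.6g}"


def parse_newick(text: str) -> Tree:
    """Parse a single Newick statement into an unrooted :class:`Tree`.

    Internal-node labels that are numeric and fall in [0, 100] are read as
    bootstrap supports of the subtending edge; other internal labels are
    ignored.  A bifurcating outermost node is suppressed so the result is
    genuinely unrooted.
    """
    if not text.strip():
        raise NewickError("empty Newick input")
    if not text.strip().endswith(";"):
        raise NewickError("Newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises various DataError subclasses
        if "Duplicate taxon" in str(exc):
            raise ValidationError(f"duplicate leaf labels: {exc}") from exc
        pos = ""
        col = getattr(exc, "col_num", None)
        line = getattr(exc, "line_num", None)
        if col is not None:
            pos = f" (line {line}, column {col})"
        raise NewickError(f"malformed Newick{pos}: {exc}") from exc

    tree = Tree()
    node_map: dict[object, int] = {}
    for dnode in dtree.preorder_node_iter():
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is None:
                raise NewickError("leaf without a label")
            if label in tree._node_of:
                raise ValidationError(f"duplicate leaf label: {label!r}")
            node_map[dnode] = tree.add_node(label)
        else:
            node_map[dnode] = tree.add_node()
    for dnode in dtree.preorder_node_iter():
        parent = dnode.parent_node
        if parent is None:
            continue
        support = None
        if not dnode.is_leaf() and dnode.label is not None:
            try:
                val = float(dnode.label)
            except ValueError:
                val = None
            if val is not None:
                if not (0 <= val <= 100):
                    raise ValidationError(
                        f"support out of range [0,100]: {dnode.label}"
                    )
                support = int(round(val))
        length = dnode.edge.length
        if length is not None and length < 0:
            raise ValidationError(f"negative branch length: {length}")
        tree.add_edge(node_map[parent], node_map[dnode], length, support)
    tree.suppress_unlabelled_low_degree()
    tree.validate()
    return tree


def _min_descendant(tree: Tree, v: int, parent: int, memo: dict) -> str:
    key = (v, parent)
    if key in memo:
        return memo[key]
    if tree.is_leaf(v):
        memo[key] = tree.label(v)
        return memo[key]
    memo[key] = min(
        _min_descendant(tree, w, v, memo) for w in tree.neighbors(v) if w != parent
    )
    return memo[key]


def _subtree_newick(tree: Tree, v: int, parent: int, memo: dict) -> str:
    e = tree.edge(parent, v)
    if tree.is_leaf(v):
        s = _quote_label(tree.label(v))
    else:
        kids = sorted(
            (w for w in tree.neighbors(v) if w != parent),
            key=lambda w: _min_descendant(tree, w, v, memo),
        )
        s = "(" + ",".join(_subtree_newick(tree, w, v, memo) for w in kids) + ")"
        if e.support is not None:
            s += str(e.support)
    if e.length is not None:
        s += ":" + _fmt_length(e.length)
    return s


def write_newick(tree: Tree) -> str:
    """Canonical Newick serialization.

    The tree is written from the internal node adjacent to the
    lexicographically largest leaf, with children everywhere ordered by their
    smallest descendant leaf label; supports become internal-node labels and
    lengths are printed with 6 significant digits.  Equal trees therefore
    serialize identically, and ``parse_newick(write_newick(t))`` round-trips.
    """
    n = tree.n_leaves
    if n == 0:
        raise ValidationError("cannot serialize an empty tree")
    if n == 1:
        (v,) = tree.leaves()
        return _quote_label(tree.label(v)) + ";"
    labels = sorted(tree._node_of)
    if n == 2:
        a, b = labels
        e = tree.edge(tree.node_of(a), tree.node_of(b))
        bs = _quote_label(b) + (":" + _fmt_length(e.length) if e.length is not None else "")
        return f"({_quote_label(a)},{bs});"
    anchor_leaf = tree.node_of(labels[-1])
    root = next(iter(tree.neighbors(anchor_leaf)))
    memo: dict = {}
    kids = sorted(
        tree.neighbors(root), key=lambda w: _min_descendant(tree, w, root, memo)
    )
    return "(" + ",".join(_subtree_newick(tree, w, root, memo) for w in kids) + ");"


def read_newick_trees(source: str | io.TextIOBase) -> list[Tree]:
    """Read multi-tree input: one Newick statement per non-empty line."""
    if isinstance(source, str):
        with open(source) as fh:
            lines = fh.readlines()
    else:
        lines = source.readlines()
    return [parse_newick(ln) for ln in lines if ln.strip()]


def write_newick_trees(trees: Sequence[Tree], path: str) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# -- comparison & distances ------------------------------------------------


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Unrooted symmetric-difference RF distance (non-trivial bipartitions)."""
    if t1.taxa != t2.taxa:
        raise ValidationError(
            f"leaf sets differ: {set(t1.taxa) ^ set(t2.taxa)}"
        )
    return len(t1.bipartition_set() ^ t2.bipartition_set())


def path_length_matrix(tree: Tree, mode: str = "topological") -> DistanceMatrix:
    """Leaf-to-leaf path lengths.

    ``topological`` counts edges on the connecting path; ``branch_length``
    sums branch lengths and requires every edge to carry one.
    """
    if mode not in ("topological", "branch_length"):
        raise ValidationError(f"unknown mode: {mode}")
    if mode == "branch_length":
        for u, v, e in tree.edges():
            if e.length is None:
                raise ValidationError("branch_length mode requires all edge lengths")
    import numpy as np

    leaves = tree.leaves()
    taxa = [tree.label(v) for v in leaves]
    index = {v: i for i, v in enumerate(leaves)}
    n = len(leaves)
    out = np.zeros((n, n))
    for src in leaves:
        dist = {src: 0.0}
        stack = [src]
        while stack:
            w = stack.pop()
            for x, e in tree._adj[w].items():
                if x not in dist:
                    step = 1.0 if mode == "topological" else float(e.length)
                    dist[x] = dist[w] + step
                    stack.append(x)
        i = index[src]
        for v in leaves:
            out[i, index[v]] = dist[v]
    return DistanceMatrix(taxa, out)
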