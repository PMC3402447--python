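"""Most-similar-supertree (MSSA) scoring and heuristic tree search.

A candidate supertree is scored against each source gene tree by pruning it
to the source's taxa, computing both path-length matrices, and summing the
element-wise differences over unordered leaf pairs (absolute differences by
default, squared optionally; topological path lengths by default, branch
lengths optionally).  The best supertree minimizes the total over sources.

The search is steepest-descent hill climbing over NNI (default) or SPR
neighborhoods, restarted from the Neighbor-Joining tree of the sources'
pseudo-sequence distances (first restart) and from random binary trees
(subsequent restarts).  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .mrp import build_mrp_matrix
from .treeio import Tree, ValidationError, path_length_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "mssa_score",
    "tree_neighbors",
    "mssa_search",
    "MSSAResult",
    "enumerate_topologies",
    "random_binary_tree",
]


# -- scoring ---------------------------------------------------------------


class _ScoreContext:
    """Pre-digested sources for repeated scoring of candidate supertrees."""

    def __init__(self, sources: Sequence[Tree], full_taxa: Sequence[str], mode: str, fit: str):
        if mode not in ("topological", "branch_length"):
            raise ValidationError(f"unknown mode: {mode}")
        if fit not in ("absolute", "squared"):
            raise ValidationError(f"unknown fit: {fit}")
        self.mode, self.fit = mode, fit
        self.full = tuple(sorted(full_taxa))
        index = {t: i for i, t in enumerate(self.full)}
        groups: dict[frozenset, list[np.ndarray]] = {}
        for src in sources:
            extra = set(src.taxa) - set(self.full)
            if extra:
                raise ValidationError(f"source taxa missing from supertree: {sorted(extra)}")
            groups.setdefault(frozenset(src.taxa), []).append(
                path_length_matrix(src, mode).values
            )
        self.groups = [
            (tuple(sorted(ts)), [index[t] for t in sorted(ts)], np.stack(mats))
            for ts, mats in sorted(groups.items(), key=lambda kv: tuple(sorted(kv[0])))
        ]

    def score(self, tree: Tree) -> float:
        pm = path_length_matrix(tree, self.mode).values  # taxa in sorted order
        total = 0.0
        for taxa, idx, mats in self.groups:
            if len(taxa) == len(self.full):
                sub = pm
            elif self.mode == "branch_length":
                # pruning preserves leaf-to-leaf branch-length distances
                sub = pm[np.ix_(idx, idx)]
            else:
                sub = path_length_matrix(tree.restrict(taxa), self.mode).values
            diff = mats - sub[None, :, :]
            if self.fit == "absolute":
                total += np.abs(diff).sum() / 2.0
            else:
                total += (diff**2).sum() / 2.0
        return float(total)


def mssa_score(
    supertree: Tree,
    sources: Sequence[Tree],
    mode: str = "topological",
    fit: str = "absolute",
) -> float:
    """Total path-length-matrix discrepancy between a supertree and its sources."""
    ctx = _ScoreContext(sources, supertree.taxa, mode, fit)
    return ctx.score(supertree)


# -- neighborhoods ---------------------------------------------------------


def _require_binary(tree: Tree, n_min: int = 4) -> None:
    if tree.n_leaves < n_min:
        raise ValidationError(f"need >= {n_min} leaves, got {tree.n_leaves}")
    if not tree.is_binary():
        raise ValidationError("tree must be binary (fully resolved)")


def _nni_neighbors(tree: Tree) -> Iterator[Tree]:
    for u, v, _ in list(tree.internal_edges()):
        b = [w for w in tree.neighbors(u) if w != v][1]
        cs = [w for w in tree.neighbors(v) if w != u]
        for c in cs:
            t = tree.copy()
            eb, ec = t.edge(u, b), t.edge(v, c)
            t.remove_edge(u, b)
            t.remove_edge(v, c)
            t.add_edge(u, c, ec.length, ec.support)
            t.add_edge(v, b, eb.length, eb.support)
            yield t


def _splice(t: Tree, v: int) -> tuple[int, int]:
    """Remove an unlabelled degree-2 node, merging its two edges."""
    (a, ea), (b, eb) = list(t._adj[v].items())
    if ea.length is None and eb.length is None:
        length = None
    else:
        length = (ea.length or 0.0) + (eb.length or 0.0)
    sups = [s for s in (ea.support, eb.support) if s is not None]
    t.remove_node(v)
    t.add_edge(a, b, length, max(sups) if sups else None)
    return a, b


def _spr_neighbors(tree: Tree) -> Iterator[Tree]:
    seen = {tree.bipartition_set()}
    for u, v, _ in list(tree.edges()):
        for tail, head in ((u, v), (v, u)):
            # prune the subtree on the `head` side; `tail` stays behind
            if tree.is_leaf(tail):
                continue  # would leave a single-leaf remainder
            t0 = tree.copy()
            e_pruned = t0.edge(tail, head).copy()
            t0.remove_edge(tail, head)
            a, _ = _splice(t0, tail)  # tail is internal, now degree 2
            remaining = _component(t0, a)
            for x, y in [(x, y) for x, y, _ in t0.edges() if x in remaining]:
                t = t0.copy()
                exy = t.edge(x, y)
                t.remove_edge(x, y)
                w = t.add_node()
                half = None if exy.length is None else exy.length / 2.0
                t.add_edge(x, w, half, exy.support)
                t.add_edge(w, y, half)
                t.add_edge(w, head, e_pruned.length, e_pruned.support)
                sig = t.bipartition_set()
                if sig not in seen:
                    seen.add(sig)
                    yield t


def _component(tree: Tree, start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        w = stack.pop()
        for x in tree.neighbors(w):
            if x not in seen:
                seen.add(x)
                stack.append(x)
    return seen


def tree_neighbors(tree: Tree, move: str = "NNI") -> list[Tree]:
    """All distinct topologies one NNI or SPR move away (leaf set preserved)."""
    _require_binary(tree)
    if move == "NNI":
        return list(_nni_neighbors(tree))
    if move == "SPR":
        return list(_spr_neighbors(tree))
    raise ValidationError(f"unknown move: {move}")


# -- search ----------------------------------------------------------------


def random_binary_tree(taxa: Sequence[str], rng: np.random.Generator) -> Tree:
    """Uniform-ish random binary topology by random sequential leaf addition."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValidationError("need >= 3 taxa")
    order = list(taxa)
    rng.shuffle(order)
    t = Tree()
    center = t.add_node()
    for lab in order[:3]:
        t.add_edge(center, t.add_node(lab))
    for lab in order[3:]:
        edges = list(t.edges())
        x, y, _ = edges[int(rng.integers(len(edges)))]
        t.remove_edge(x, y)
        w = t.add_node()
        t.add_edge(x, w)
        t.add_edge(w, y)
        t.add_edge(w, t.add_node(lab))
    return t


@dataclass
class MSSAResult:
    """Best tree, its score, and the per-restart (restart, iterations, score) trace."""

    tree: Tree
    score: float
    trace: list[tuple[int, int, float]] = field(default_factory=list)

    def __iter__(self):  # allow `tree, score = mssa_search(...)`
        return iter((self.tree, self.score))


def _hill_climb(start: Tree, ctx: _ScoreContext, move: str) -> tuple[Tree, float, int]:
    current, cur_score = start, ctx.score(start)
    iters = 0
    while True:
        best_nb, best_score = None, cur_score
        for nb in tree_neighbors(current, move):
            s = ctx.score(nb)
            if s < best_score:
                best_nb, best_score = nb, s
        if best_nb is None:
            return current, cur_score, iters
        current, cur_score = best_nb, best_score
        iters += 1


def mssa_search(
    sources: Sequence[Tree],
    full_taxa: Sequence[str] | None = None,
    restarts: int = 5,
    seed: int = 0,
    move: str = "NNI",
    mode: str = "topological",
    fit: str = "absolute",
) -> MSSAResult:
    """Heuristic MSSA supertree search.

    Restart 1 starts from the NJ tree of the sources' pseudo-sequence
    distances (all bipartitions, no support filter); later restarts start
    from seeded random binary trees.  Each restart runs steepest-descent
    hill climbing until no neighbor improves the score; the best tree over
    restarts is returned (first encountered wins ties).
    """
    if not sources:
        raise ValidationError("no source trees")
    if restarts < 1:
        raise ValidationError("restarts must be >= 1")
    union: set[str] = set()
    for s in sources:
        union |= set(s.taxa)
    if full_taxa is None:
        full_taxa = sorted(union)
    elif set(full_taxa) != union:
        raise ValidationError("full_taxa must equal the union of source taxa")
    full_taxa = sorted(full_taxa)

    ctx = _ScoreContext(sources, full_taxa, mode, fit)
    if len(full_taxa) == 3:  # a single unrooted topology exists
        star = random_binary_tree(full_taxa, np.random.default_rng(0))
        return MSSAResult(star, ctx.score(star), [(0, 0, ctx.score(star))])
    rng = np.random.default_rng(seed)
    best: tuple[Tree, float] | None = None
    trace: list[tuple[int, int, float]] = []
    for r in range(restarts):
        start = None
        if r == 0:
            try:
                from .nj import nj_tree, p_distance

                m = build_mrp_matrix(sources, full_taxa, min_support=None)
                start = nj_tree(p_distance(m))
            except ValidationError as exc:
                logger.warning("NJ start failed (%s); falling back to random start", exc)
        if start is None:
            start = random_binary_tree(full_taxa, rng)
        tree, score, iters = _hill_climb(start, ctx, move)
        trace.append((r, iters, score))
        if best is None or score < best[1]:
            best = (tree, score)
    assert best is not None
    return MSSAResult(best[0], best[1], trace)


# -- exhaustive enumeration (oracle-grade, small n only) -------------------


def enumerate_topologies(taxa: Sequence[str]) -> Iterator[Tree]:
    """Yield every unrooted binary topology over the taxa ((2n-5)!! of them)."""
    taxa = sorted(taxa)
    if len(taxa) < 3:
        raise ValidationError("need >= 3 taxa")

    def _grow(tree: Tree, rest: list[str]) -> Iterator[Tree]:
        if not rest:
            yield tree
            return
        lab, tail = rest[0], rest[1:]
        for x, y, _ in list(tree.edges()):
            t = tree.copy()
            t.remove_edge(x, y)
            w = t.add_node()
            t.add_edge(x, w)
            t.add_edge(w, y)
            t.add_edge(w, t.add_node(lab))
            yield from _grow(t, tail)

    base = Tree()
    c = base.add_node()
    for lab in taxa[:3]:
        base.add_edge(c, base.add_node(lab))
    yield from _grow(base, taxa[3:])
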