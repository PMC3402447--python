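"""Pseudo-sequence distances, Neighbor-Joining, and column-resampling bootstrap.

The distance between two pseudo-sequences is the uncorrected p-distance
with pairwise deletion: columns where either taxon is ``?`` are ignored,
and the distance is mismatches / comparable columns.  On a two-state
alphabet with symmetric states no correction is attempted.

Neighbor-Joining is the standard Saitou-Nei agglomeration on the Q
criterion; ties are broken by the smallest (row, column) index pair in the
current node ordering (initial taxa sorted lexicographically, joined nodes
appended), which makes the output a deterministic function of the matrix.
Negative branch-length estimates are clamped to zero.

Bootstrap supports resample matrix columns with replacement, rebuild the
distances and the NJ tree per replicate, and report for each internal edge
of the point-estimate tree the percentage of replicates whose tree contains
the same bipartition.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np

from .distmat import DistanceMatrix
from .mrp import PseudoSequenceMatrix
from .treeio import Tree, ValidationError

__all__ = ["p_distance", "nj_tree", "bootstrap_nj"]

logger = logging.getLogger(__name__)


def _pair_masks(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Per unordered taxon pair: column masks of comparable and mismatching cells."""
    n = data.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ok = np.empty((len(pairs), data.shape[1]), dtype=np.float64)
    bad = np.empty_like(ok)
    for k, (i, j) in enumerate(pairs):
        comparable = (data[i] >= 0) & (data[j] >= 0)
        ok[k] = comparable
        bad[k] = comparable & (data[i] != data[j])
    return ok, bad, pairs


def _pdist_from_counts(
    comp: np.ndarray, mism: np.ndarray, pairs, taxa
) -> DistanceMatrix:
    n = len(taxa)
    vals = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        if comp[k] == 0:
            raise ValidationError(
                f"taxa {taxa[i]!r} and {taxa[j]!r} share no comparable columns"
            )
        vals[i, j] = vals[j, i] = mism[k] / comp[k]
    return DistanceMatrix(taxa, vals, _skip_checks=True)


def p_distance(matrix: PseudoSequenceMatrix) -> DistanceMatrix:
    """Uncorrected mismatch proportion with pairwise deletion of ``?`` columns."""
    if matrix.shape[1] == 0:
        raise ValidationError("empty matrix: no columns to compare")
    ok, bad, pairs = _pair_masks(matrix.data)
    return _pdist_from_counts(ok.sum(axis=1), bad.sum(axis=1), pairs, matrix.taxa)


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou-Nei Neighbor-Joining with deterministic tie-breaking."""
    n = len(d)
    if n < 3:
        raise ValidationError(f"NJ requires >= 3 taxa, got {n}")
    D = d.values.copy()
    tree = Tree()
    # active[i] -> tree node; order = taxa sorted (DistanceMatrix order is
    # caller-defined, so sort here for a label-determined result)
    order = sorted(range(n), key=lambda i: d.taxa[i])
    D = D[np.ix_(order, order)]
    nodes = [tree.add_node(d.taxa[i]) for i in order]
    active = list(range(len(nodes)))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        k = int(np.argmin(q))  # first minimum in row-major order = tie-break
        ai, aj = divmod(k, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        u = tree.add_node()
        tree.add_edge(u, nodes[i], max(li, 0.0))
        tree.add_edge(u, nodes[j], max(lj, 0.0))
        # new distances to remaining nodes
        newrow = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(newrow)] = newrow
        D[: len(newrow), -1] = newrow
        D[-1, -1] = 0.0
        nodes.append(u)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    # final three-way join: closed-form pendant lengths
    a, b, c = active
    center = tree.add_node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for x, lx in ((a, la), (b, lb), (c, lc)):
        tree.add_edge(center, nodes[x], max(lx, 0.0))
    return tree


def bootstrap_nj(
    matrix: PseudoSequenceMatrix, replicates: int = 1000, seed: int = 0
) -> Tree:
    """NJ point-estimate tree annotated with column-resampling bootstrap supports.

    Each replicate draws ``n_columns`` columns with replacement, recomputes
    p-distances and the NJ tree, and tallies the point tree's bipartitions.
    Supports are percentages rounded to the nearest integer (ties away from
    zero).  Replicates in which some pair loses all comparable columns are
    skipped with a logged warning; percentages are over completed replicates.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    nt, nc = matrix.shape
    if nc == 0:
        raise ValidationError("matrix has no columns")
    rng = np.random.default_rng(seed)
    ok, bad, pairs = _pair_masks(matrix.data)
    point = nj_tree(_pdist_from_counts(ok.sum(axis=1), bad.sum(axis=1), pairs, matrix.taxa))

    point_bips = point.bipartition_set()
    counts = {bip: 0 for bip in point_bips}
    skipped = 0
    for _ in range(replicates):
        draw = rng.integers(0, nc, size=nc)
        mult = np.bincount(draw, minlength=nc).astype(np.float64)
        comp = ok @ mult
        if np.any(comp == 0):
            skipped += 1
            continue
        mism = bad @ mult
        rep_tree = nj_tree(_pdist_from_counts(comp, mism, pairs, matrix.taxa))
        rep_bips = rep_tree.bipartition_set()
        for bip in point_bips:
            if bip in rep_bips:
                counts[bip] += 1
    done = replicates - skipped
    if skipped:
        logger.warning(
            "bootstrap: skipped %d/%d replicates with incomparable pairs",
            skipped,
            replicates,
        )
    if done == 0:
        raise ValidationError("all bootstrap replicates were skipped")

    out = point.copy()
    smallest = min(out.taxa)
    all_taxa = frozenset(out.taxa)
    for u, v, e in out.internal_edges():
        side = out.side_labels(u, v)
        if smallest not in side:
            side = all_taxa - side
        if side in counts:
            pct = 100.0 * counts[side] / done
            e.support = int(np.floor(pct + 0.5))  # round half away from zero
    return out
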