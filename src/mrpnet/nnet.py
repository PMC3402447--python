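"""Neighbor-Net: circular split systems from distance matrices.

The method generalizes Neighbor-Joining: an agglomerative pass produces a
circular ordering of the taxa, then non-negative least squares assigns
weights to the n(n-1)/2 splits realizable as intervals of that ordering.
Incompatible splits with positive weight are what render as "boxes" in a
split-network viewer and flag conflicting (non-tree-like) signal such as
recombination or horizontal transfer.

Agglomeration follows the original published scheme: clusters of one or two
linked nodes, cluster pairs chosen by the Neighbor-Joining Q criterion on
average-linkage distances, node pairs within the chosen clusters by the
same criterion with companion nodes treated as singleton clusters, and
3-node paths collapsed with 2/3-1/3 distance-update weights.  Ties are
broken by scanning order (lexicographic taxon order), making the output a
deterministic function of the matrix.

On additive (tree-metric) input the ordering is compatible with the tree
and the weighted splits reproduce the tree's bipartitions and branch
lengths; the fit residual is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.optimize

from .distmat import DistanceMatrix
from .treeio import ValidationError

__all__ = [
    "Split",
    "SplitSystem",
    "neighbor_net",
    "circular_split_distance",
    "split_compatible",
    "write_splits_nexus",
    "read_splits_nexus",
]


@dataclass(frozen=True)
class Split:
    """Weighted bipartition of the full taxon set.

    Canonical polarity: ``side_a`` holds the lexicographically smallest
    taxon.  ``trivial`` means one side is a single taxon (a pendant edge in
    tree terms); trivial splits are compatible with everything.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]
    weight: float = 0.0

    def __post_init__(self):
        if not self.side_a or not self.side_b:
            raise ValidationError("split sides must be non-empty")
        if self.side_a & self.side_b:
            raise ValidationError("split sides overlap")
        if min(self.side_a | self.side_b) not in self.side_a:
            raise ValidationError("canonical polarity violated")
        if not (self.weight >= 0):
            raise ValidationError(f"split weight must be >= 0, got {self.weight}")

    @classmethod
    def from_sides(cls, one, other, weight: float = 0.0) -> "Split":
        a, b = frozenset(one), frozenset(other)
        if min(a | b) in b:
            a, b = b, a
        return cls(a, b, weight)

    @property
    def is_trivial(self) -> bool:
        return len(self.side_a) == 1 or len(self.side_b) == 1

    def separates(self, x: str, y: str) -> bool:
        return (x in self.side_a) != (y in self.side_a)


def split_compatible(s: Split, t: Split) -> bool:
    """True iff the two splits can coexist in one tree (some intersection empty)."""
    return (
        not (s.side_a & t.side_a)
        or not (s.side_a & t.side_b)
        or not (s.side_b & t.side_a)
        or not (s.side_b & t.side_b)
    )


@dataclass
class SplitSystem:
    """Weighted splits plus the circular taxon ordering that displays them."""

    taxa: tuple[str, ...]
    circular_order: tuple[str, ...]
    splits: list[Split] = field(default_factory=list)

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        self.circular_order = tuple(self.circular_order)
        if sorted(self.circular_order) != sorted(self.taxa):
            raise ValidationError("circular_order is not a permutation of taxa")
        for s in self.splits:
            if s.side_a | s.side_b != set(self.taxa):
                raise ValidationError("split does not cover the taxon set")
            if not self.is_interval(s):
                raise ValidationError("split is not an interval of the circular order")

    def is_interval(self, s: Split) -> bool:
        pos = {t: i for i, t in enumerate(self.circular_order)}
        n = len(self.circular_order)
        for side in (s.side_a, s.side_b):
            idx = sorted(pos[t] for t in side)
            if idx[-1] - idx[0] == len(idx) - 1:
                return True
        # wrap-around intervals show as the complement being contiguous,
        # which the other side covers; reaching here means neither side is
        # contiguous without wrapping -- check wrapping explicitly
        for side in (s.side_a, s.side_b):
            marks = [t in side for t in self.circular_order]
            # count blocks of True in circular arrangement
            transitions = sum(
                1 for i in range(n) if marks[i] and not marks[i - 1]
            )
            if transitions == 1:
                return True
        return False

    def nontrivial(self) -> list[Split]:
        return [s for s in self.splits if not s.is_trivial]

    def incompatible_pairs(self) -> list[tuple[Split, Split]]:
        nt = self.nontrivial()
        return [
            (s, t)
            for i, s in enumerate(nt)
            for t in nt[i + 1 :]
            if not split_compatible(s, t)
        ]


# -- agglomerative ordering ------------------------------------------------


def _reduce_path(d: np.ndarray, x: int, y: int, z: int) -> None:
    """Collapse path x-y-z into two nodes stored in slots x and z (2/3-1/3 weights)."""
    u = (2.0 / 3.0) * d[x] + (1.0 / 3.0) * d[y]
    v = (2.0 / 3.0) * d[z] + (1.0 / 3.0) * d[y]
    uv = (d[x, y] + d[x, z] + d[y, z]) / 3.0
    d[x, :] = u
    d[:, x] = u
    d[z, :] = v
    d[:, z] = v
    d[y, :] = 0.0
    d[:, y] = 0.0
    d[x, z] = d[z, x] = uv
    d[x, x] = d[z, z] = 0.0


def _nn_ordering(d0: np.ndarray) -> list[int]:
    """Circular taxon ordering (as indices into d0) via Neighbor-Net agglomeration."""
    n = d0.shape[0]
    if n <= 3:
        return list(range(n))
    d = d0.astype(float).copy()
    clusters: list[list[int]] = [[i] for i in range(n)]  # active endpoint nodes
    orders: list[list[int]] = [[i] for i in range(n)]  # original taxa, path order
    DM = d.copy()

    while len(clusters) > 1:
        m = len(clusters)
        if m == 2:
            e1, e2 = 0, 1
        else:
            r = DM.sum(axis=1)
            q = DM - (r[:, None] + r[None, :]) / (m - 2)
            np.fill_diagonal(q, np.inf)
            k = int(np.argmin(q))  # first minimum row-major: deterministic ties
            e1, e2 = divmod(k, m)
            if e1 > e2:
                e1, e2 = e2, e1

        c1, c2 = clusters[e1], clusters[e2]
        n1, n2 = len(c1), len(c2)
        if n1 == 1 and n2 == 1:
            clusters[e1] = c1 + c2
            orders[e1] = orders[e1] + orders[e2]
        else:
            others = [clusters[k] for k in range(m) if k not in (e1, e2)]
            cand = c1 + c2
            ltmp = len(cand) + len(others)
            r2 = np.empty(len(cand))
            for a, x in enumerate(cand):
                s = sum(d[x, y] for y in cand if y != x)
                s += sum(d[x, C].mean() for C in others)
                r2[a] = s
            if ltmp > 2:
                r2 = r2 / (ltmp - 2)
            best_val, best = np.inf, (0, 0)
            for qq in range(n2):  # column-major scan: first minimum wins
                for pp in range(n1):
                    val = d[c1[pp], c2[qq]] - r2[pp] - r2[n1 + qq]
                    if val < best_val:
                        best_val, best = val, (pp, qq)
            x_pos, y_pos = best
            # orient cluster paths so the chosen endpoints become adjacent
            if n1 == 2 and x_pos == 0:
                c1p, ord1 = [c1[1], c1[0]], list(reversed(orders[e1]))
            else:
                c1p, ord1 = list(c1), list(orders[e1])
            if n2 == 2 and y_pos == 1:
                c2p, ord2 = [c2[1], c2[0]], list(reversed(orders[e2]))
            else:
                c2p, ord2 = list(c2), list(orders[e2])
            path = c1p + c2p
            while len(path) > 2:
                _reduce_path(d, path[0], path[1], path[2])
                path = [path[0], path[2]] + path[3:]
            clusters[e1] = path
            orders[e1] = ord1 + ord2

        for i in range(m):
            if i == e1:
                continue
            DM[e1, i] = DM[i, e1] = d[np.ix_(clusters[e1], clusters[i])].mean()
        DM[e1, e1] = 0.0
        DM = np.delete(np.delete(DM, e2, axis=0), e2, axis=1)
        del clusters[e2]
        del orders[e2]

    return orders[0]


# -- split weights ---------------------------------------------------------


def _interval_splits(n: int) -> list[tuple[int, int]]:
    """All circular splits of an n-cycle as position intervals [i..j], 1 <= i <= j <= n-1.

    Excluding position 0 from the listed side makes each of the n(n-1)/2
    circular splits appear exactly once.
    """
    return [(i, j) for i in range(1, n) for j in range(i, n)]


def neighbor_net(
    d: DistanceMatrix, weight_floor: float = 1e-8
) -> SplitSystem:
    """Circular split system fitted to a distance matrix.

    Phase 1 computes the circular ordering by agglomeration; phase 2 fits
    non-negative weights to all interval splits of the ordering by least
    squares.  Non-trivial splits with weight <= ``weight_floor`` are
    dropped; trivial (pendant) splits are always kept, whatever their
    weight.  For n == 3 the three pendant weights have the closed form
    a = (d_AB + d_AC - d_BC)/2 (clamped at zero) and no agglomeration runs.
    """
    taxa = list(d.taxa)
    n = len(taxa)
    if n < 3:
        raise ValidationError(f"neighbor_net requires >= 3 taxa, got {n}")
    if n == 3:
        D = d.values
        splits = []
        for i in range(3):
            j, k = [x for x in range(3) if x != i]
            w = max(0.0, 0.5 * (D[i, j] + D[i, k] - D[j, k]))
            splits.append(
                Split.from_sides({taxa[i]}, set(taxa) - {taxa[i]}, w)
            )
        return SplitSystem(tuple(sorted(taxa)), tuple(taxa), _sorted_splits(splits))

    order_idx = _nn_ordering(d.values)
    cycle = [taxa[i] for i in order_idx]
    intervals = _interval_splits(n)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]  # cycle positions
    A = np.zeros((len(pairs), len(intervals)))
    for col, (lo, hi) in enumerate(intervals):
        for row, (p, q) in enumerate(pairs):
            inside_p = lo <= p <= hi
            inside_q = lo <= q <= hi
            if inside_p != inside_q:
                A[row, col] = 1.0
    b = np.array([d.values[order_idx[p], order_idx[q]] for p, q in pairs])
    weights, _ = scipy.optimize.nnls(A, b, maxiter=10 * len(intervals))

    splits = []
    for (lo, hi), w in zip(intervals, weights):
        side = set(cycle[lo : hi + 1])
        s = Split.from_sides(side, set(taxa) - side, float(w))
        if s.is_trivial or s.weight > weight_floor:
            splits.append(s)
    return SplitSystem(tuple(sorted(taxa)), tuple(cycle), _sorted_splits(splits))


def _sorted_splits(splits: list[Split]) -> list[Split]:
    return sorted(splits, key=lambda s: (len(s.side_a), tuple(sorted(s.side_a))))


def circular_split_distance(s: SplitSystem) -> DistanceMatrix:
    """Metric induced by the split system: d(i,j) = sum of weights of splits separating i, j."""
    taxa = list(s.taxa)
    n = len(taxa)
    vals = np.zeros((n, n))
    for sp in s.splits:
        in_a = np.array([t in sp.side_a for t in taxa])
        sep = in_a[:, None] != in_a[None, :]
        vals[sep] += sp.weight
    return DistanceMatrix(taxa, vals)


# -- NEXUS SPLITS I/O ------------------------------------------------------


def write_splits_nexus(s: SplitSystem, path: str) -> None:
    """NEXUS with TAXA and SPLITS blocks in the SplitsTree dialect.

    The CYCLE statement records the circular ordering; each MATRIX line is
    one weighted split, listing the side that excludes the first cycle
    taxon, as 1-based taxon indices in cycle order.
    """
    taxa = list(s.taxa)
    idx1 = {t: i + 1 for i, t in enumerate(taxa)}
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"DIMENSIONS NTAX={len(taxa)};",
        "TAXLABELS",
        *(f"  '{t}'" for t in taxa),
        ";",
        "END;",
        "",
        "BEGIN SPLITS;",
        f"DIMENSIONS NTAX={len(taxa)} NSPLITS={len(s.splits)};",
        "FORMAT LABELS=NO WEIGHTS=YES;",
        "CYCLE " + " ".join(str(idx1[t]) for t in s.circular_order) + ";",
        "MATRIX",
    ]
    first = s.circular_order[0]
    for k, sp in enumerate(s.splits, start=1):
        side = sp.side_b if first in sp.side_a else sp.side_a
        members = [t for t in s.circular_order if t in side]
        ids = " ".join(str(idx1[t]) for t in members)
        lines.append(f"  [{k}]\t{sp.weight:.10g}\t{ids},")
    lines += [";", "END;", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_splits_nexus(path: str) -> SplitSystem:
    """Parse the dialect produced by :func:`write_splits_nexus`."""
    with open(path) as fh:
        text = fh.read()
    taxa: list[str] = []
    cycle_ids: list[int] = []
    splits: list[tuple[float, list[int]]] = []
    mode = None
    for raw in text.splitlines():
        ln = raw.strip()
        up = ln.upper()
        if up.startswith("TAXLABELS"):
            mode = "taxa"
            continue
        if up.startswith("CYCLE"):
            cycle_ids = [int(x) for x in ln.rstrip(";").split()[1:]]
            continue
        if up.startswith("MATRIX"):
            mode = "matrix"
            continue
        if ln == ";":
            mode = None
            continue
        if mode == "taxa" and ln:
            taxa.append(ln.strip("'"))
        elif mode == "matrix" and ln:
            body = ln.rstrip(",")
            if "]" in body:
                body = body.split("]", 1)[1]
            parts = body.split()
            splits.append((float(parts[0]), [int(x) for x in parts[1:]]))
    cycle = tuple(taxa[i - 1] for i in cycle_ids)
    out = []
    for w, ids in splits:
        side = {taxa[i - 1] for i in ids}
        out.append(Split.from_sides(side, set(taxa) - side, w))
    return SplitSystem(tuple(taxa), cycle, out)
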