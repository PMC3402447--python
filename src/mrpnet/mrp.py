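"""Well-supported bipartition extraction and the Baum-Ragan pseudo-sequence matrix.

Each internal edge of a gene tree induces a bipartition of its leaf set.
Bipartitions whose bootstrap support exceeds a threshold (strictly greater
than, default 70) become columns of a two-state character matrix: taxa on
one side are coded ``A``, the other side ``T``, and taxa absent from that
gene ``?``.  Because every downstream distance treats the two states
symmetrically, the A/T polarity is arbitrary; we fix it canonically (the
side containing the lexicographically smallest taxon of the gene is ``A``)
so output is reproducible bit-for-bit.

Columns are deliberately *not* deduplicated: a split recovered by many genes
appears in many columns and so carries proportional weight in the distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .treeio import Tree, ValidationError

__all__ = [
    "Bipartition",
    "PseudoSequenceMatrix",
    "extract_bipartitions",
    "build_mrp_matrix",
]

# cell encoding used throughout: A=0, T=1, ?=-1
_CHAR = {0: "A", 1: "T", -1: "?"}
_CODE = {"A": 0, "T": 1, "?": -1}


@dataclass(frozen=True)
class Bipartition:
    """One internal edge's split, with provenance.

    ``side_a`` always contains the lexicographically smallest taxon of the
    union (canonical polarity); both sides have >= 2 taxa (non-trivial).
    """

    side_a: frozenset[str]
    side_b: frozenset[str]
    support: int | None
    source_gene: str = ""

    def __post_init__(self):
        if self.side_a & self.side_b:
            raise ValidationError("bipartition sides overlap")
        if len(self.side_a) < 2 or len(self.side_b) < 2:
            raise ValidationError("trivial bipartition (a side has < 2 taxa)")
        if min(self.side_a | self.side_b) not in self.side_a:
            raise ValidationError("canonical polarity violated: smallest taxon not in side_a")
        if self.support is not None and not (0 <= self.support <= 100):
            raise ValidationError(f"support out of range: {self.support}")

    @classmethod
    def from_sides(
        cls,
        one: Iterable[str],
        other: Iterable[str],
        support: int | None = None,
        source_gene: str = "",
    ) -> "Bipartition":
        a, b = frozenset(one), frozenset(other)
        if min(a | b) in b:
            a, b = b, a
        return cls(a, b, support, source_gene)

    @property
    def taxa(self) -> frozenset[str]:
        return self.side_a | self.side_b

    def separates(self, x: str, y: str) -> bool:
        return (x in self.side_a) != (y in self.side_a)

    def as_canonical_set(self) -> frozenset[str]:
        return self.side_a


def extract_bipartitions(
    tree: Tree, min_support: int | None = 70, source_gene: str = ""
) -> list[Bipartition]:
    """Bipartitions of internal edges passing the support filter.

    The filter is strict: an edge is retained only when ``support >
    min_support``.  Edges carrying no support value are treated as failing
    the filter (conservative reading of "well-supported").  Pass
    ``min_support=None`` to retain every non-trivial bipartition regardless
    of support, including unsupported edges.
    """
    if min_support is not None and not (0 <= min_support <= 100):
        raise ValidationError(f"min_support must be in [0,100], got {min_support}")
    out = []
    all_taxa = frozenset(tree.taxa)
    # deterministic edge order: sort by the canonical side's sorted labels
    items = []
    for u, v, e in tree.internal_edges():
        side = tree.side_labels(u, v)
        other = all_taxa - side
        if len(side) < 2 or len(other) < 2:
            continue
        if min_support is not None and (e.support is None or e.support <= min_support):
            continue
        items.append(Bipartition.from_sides(side, other, e.support, source_gene))
    items.sort(key=lambda b: (len(b.side_a), tuple(sorted(b.side_a))))
    return items


class PseudoSequenceMatrix:
    """Taxa x columns character matrix over {A, T, ?}.

    Rows follow ``taxa`` order (the full analysis taxon set); each column
    records one retained bipartition of one gene.  ``data`` holds the int8
    encoding A=0, T=1, ?=-1.
    """

    __slots__ = ("taxa", "columns", "data", "per_gene_counts")

    def __init__(
        self,
        taxa: Sequence[str],
        columns: Sequence[Bipartition],
        data: np.ndarray,
        per_gene_counts: dict[str, int] | None = None,
    ):
        self.taxa = tuple(taxa)
        self.columns = list(columns)
        data = np.asarray(data, dtype=np.int8)
        if data.shape != (len(self.taxa), len(self.columns)):
            raise ValidationError(
                f"matrix shape {data.shape} != ({len(self.taxa)},{len(self.columns)})"
            )
        self.data = data
        self.per_gene_counts = dict(per_gene_counts or {})

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return "".join(_CHAR[int(c)] for c in self.data[i])

    # -- text formats ------------------------------------------------------

    def to_phylip(self) -> str:
        """Relaxed PHYLIP-like: header, then 'label  sequence' per taxon."""
        nt, nc = self.shape
        lines = [f" {nt} {nc}"]
        for t in self.taxa:
            lines.append(f"{t}  {self.row(t)}")
        return "\n".join(lines) + "\n"

    def to_fasta(self) -> str:
        return "".join(f">{t}\n{self.row(t)}\n" for t in self.taxa)

    @classmethod
    def _from_rows(cls, taxa: list[str], rows: list[str]) -> "PseudoSequenceMatrix":
        if len({len(r) for r in rows}) > 1:
            raise ValidationError("ragged pseudo-sequence rows")
        try:
            data = np.array(
                [[_CODE[c] for c in row] for row in rows], dtype=np.int8
            )
        except KeyError as exc:
            raise ValidationError(f"invalid matrix character: {exc}") from exc
        if data.size == 0:
            data = data.reshape(len(taxa), 0)
        return cls(taxa, [None] * data.shape[1], data)  # type: ignore[list-item]

    @classmethod
    def from_phylip(cls, text: str) -> "PseudoSequenceMatrix":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        nt, nc = (int(x) for x in lines[0].split()[:2])
        taxa, rows = [], []
        for ln in lines[1 : nt + 1]:
            name, seq = ln.split(None, 1)
            taxa.append(name)
            rows.append(seq.strip())
        m = cls._from_rows(taxa, rows)
        if m.shape != (nt, nc):
            raise ValidationError("PHYLIP header does not match matrix body")
        return m

    @classmethod
    def from_fasta(cls, text: str) -> "PseudoSequenceMatrix":
        taxa, rows, cur = [], [], []
        for ln in text.splitlines():
            if ln.startswith(">"):
                taxa.append(ln[1:].strip())
                rows.append("")
            elif ln.strip():
                rows[-1] += ln.strip()
        return cls._from_rows(taxa, rows)


def build_mrp_matrix(
    gene_trees: Sequence[Tree],
    full_taxa: Sequence[str] | None = None,
    min_support: int | None = 70,
    gene_ids: Sequence[str] | None = None,
) -> PseudoSequenceMatrix:
    """Assemble the pseudo-sequence matrix from per-gene bipartitions.

    Columns are concatenated in gene order (then deterministic edge order
    within each gene).  Cells: ``A`` if the taxon lies on the canonical side
    of the column's bipartition, ``T`` on the other side, ``?`` if the taxon
    is absent from that gene's leaf set.
    """
    if gene_ids is None:
        gene_ids = [f"g{i+1:04d}" for i in range(len(gene_trees))]
    if len(gene_ids) != len(gene_trees):
        raise ValidationError("gene_ids length mismatch")
    if full_taxa is None:
        universe: set[str] = set()
        for t in gene_trees:
            universe |= set(t.taxa)
        full_taxa = sorted(universe)
    full_taxa = list(full_taxa)
    taxon_index = {t: i for i, t in enumerate(full_taxa)}
    for gid, tree in zip(gene_ids, gene_trees):
        extra = set(tree.taxa) - set(full_taxa)
        if extra:
            raise ValidationError(f"gene {gid} has taxa outside the analysis set: {sorted(extra)}")

    columns: list[Bipartition] = []
    per_gene: dict[str, int] = {}
    for gid, tree in zip(gene_ids, gene_trees):
        bips = extract_bipartitions(tree, min_support, source_gene=gid)
        per_gene[gid] = len(bips)
        columns.extend(bips)

    data = np.full((len(full_taxa), len(columns)), -1, dtype=np.int8)
    for j, bip in enumerate(columns):
        for t in bip.side_a:
            data[taxon_index[t], j] = 0
        for t in bip.side_b:
            data[taxon_index[t], j] = 1
    return PseudoSequenceMatrix(full_taxa, columns, data, per_gene)
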