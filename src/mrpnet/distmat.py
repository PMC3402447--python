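"""Symmetric taxon-indexed distance matrices with square-PHYLIP I/O."""

from __future__ import annotations

import io
from typing import Sequence

import numpy as np

__all__ = ["DistanceMatrix"]


class DistanceMatrix:
    """Symmetric non-negative distances over an ordered taxon set.

    Invariants checked on construction: square shape matching the taxon
    list, symmetry, zero diagonal, finite non-negative entries.
    """

    __slots__ = ("taxa", "values")

    def __init__(self, taxa: Sequence[str], values: np.ndarray, *, _skip_checks=False):
        values = np.asarray(values, dtype=float)
        taxa = list(taxa)
        if not _skip_checks:
            n = len(taxa)
            if len(set(taxa)) != n:
                raise ValueError("duplicate taxon labels")
            if values.shape != (n, n):
                raise ValueError(f"shape {values.shape} != ({n},{n})")
            if not np.all(np.isfinite(values)):
                raise ValueError("non-finite distances")
            if np.any(values < 0):
                raise ValueError("negative distances")
            if not np.allclose(values, values.T):
                raise ValueError("matrix is not symmetric")
            if np.any(np.abs(np.diag(values)) > 0):
                raise ValueError("nonzero diagonal")
            values = (values + values.T) / 2.0
        self.taxa = tuple(taxa)
        self.values = values

    def __len__(self) -> int:
        return len(self.taxa)

    def index(self, label: str) -> int:
        return self.taxa.index(label)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def subset(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(list(taxa), self.values[np.ix_(idx, idx)])

    def reorder(self, taxa: Sequence[str]) -> "DistanceMatrix":
        if set(taxa) != set(self.taxa):
            raise ValueError("reorder requires the same taxon set")
        return self.subset(taxa)

    # -- square PHYLIP format ---------------------------------------------

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)}"]
        for i, t in enumerate(self.taxa):
            row = " ".join(f"{x:.10g}" for x in self.values[i])
            lines.append(f"{t}  {row}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_phylip(cls, text: str | io.TextIOBase) -> "DistanceMatrix":
        if not isinstance(text, str):
            text = text.read()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        n = int(lines[0].split()[0])
        taxa, rows = [], []
        for ln in lines[1 : n + 1]:
            parts = ln.split()
            taxa.append(parts[0])
            rows.append([float(x) for x in parts[1 : n + 1]])
        return cls(taxa, np.array(rows))

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_phylip())

    @classmethod
    def read(cls, path: str) -> "DistanceMatrix":
        with open(path) as fh:
            return cls.from_phylip(fh.read())
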