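"""Synthetic gene-tree datasets with known species-tree truth.

The generator emulates a core-genome phylogenomic study: a binary species
tree over ``n_taxa`` taxa (default 17, the last two given long pendant
branches to play the role of distant outgroups), and ``n_genes`` gene trees
(default 100; the emulated study used 851) that are mostly concordant with
the species tree.  A seeded minority of genes is perturbed topologically --
random NNI moves for generic discordance, or SPR transfers between
designated donor/recipient lineages to mimic horizontal gene transfer.

Bootstrap supports are drawn, not recomputed: gene-tree edges whose
bipartition matches a species-tree bipartition draw from ``support_high``
(default 85-100, above the usual 70% retention threshold), perturbed edges
from ``support_low`` (default 30-80, mostly below it).  Optionally each
taxon is dropped from each gene independently with ``missing_prob``.

Everything is a deterministic function of ``seed``: the first ``n_genes``
uniform draws decide which genes are perturbed, so the discordance tally
can be recomputed independently from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .treeio import Tree, ValidationError, write_newick

__all__ = [
    "SimulationConfig",
    "GeneProvenance",
    "SyntheticDataset",
    "yule_tree",
    "perturb_tree",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale knobs for the generator; defaults mirror the emulated study."""

    n_taxa: int = 17
    n_genes: int = 100
    discordance_prob: float = 0.1
    nni_moves_per_discordant_gene: int = 1
    hgt_pairs: tuple[tuple[str, str], ...] = ()
    support_high: tuple[int, int] = (85, 100)
    support_low: tuple[int, int] = (30, 80)
    missing_prob: float = 0.0
    seed: int = 0
    n_outgroups: int = 2
    outgroup_scale: float = 4.0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValidationError("n_taxa must be >= 4")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not (0.0 <= self.discordance_prob <= 1.0):
            raise ValidationError("discordance_prob must be in [0,1]")
        if not (0.0 <= self.missing_prob < 1.0):
            raise ValidationError("missing_prob must be in [0,1)")
        if self.nni_moves_per_discordant_gene < 1:
            raise ValidationError("nni_moves_per_discordant_gene must be >= 1")
        for lo, hi in (self.support_high, self.support_low):
            if not (0 <= lo <= hi <= 100):
                raise ValidationError(f"support range out of order: ({lo},{hi})")
        if not (0 <= self.n_outgroups <= self.n_taxa):
            raise ValidationError("n_outgroups out of range")


@dataclass(frozen=True)
class GeneProvenance:
    gene_id: str
    kind: str  # concordant | nni | hgt
    moves: tuple[str, ...] = ()


@dataclass
class SyntheticDataset:
    species_tree: Tree
    gene_trees: list[Tree]
    provenance: list[GeneProvenance]
    config: SimulationConfig

    def taxa(self) -> tuple[str, ...]:
        return self.species_tree.taxa


def _taxon_labels(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"t{i + 1:0{width}d}" for i in range(n)]


def _yule(n: int, rng: np.random.Generator) -> Tree:
    labels = _taxon_labels(n)
    t = Tree()
    if n == 2:
        t.add_edge(t.add_node(labels[0]), t.add_node(labels[1]))
    else:
        leaves = [t.add_node(labels[0]), t.add_node(labels[1])]
        t.add_edge(leaves[0], leaves[1])
        for i in range(2, n):
            u = leaves[int(rng.integers(len(leaves)))]
            v = next(iter(t.neighbors(u)))
            t.remove_edge(u, v)
            w = t.add_node()
            new_leaf = t.add_node(labels[i])
            t.add_edge(v, w)
            t.add_edge(w, u)
            t.add_edge(w, new_leaf)
            leaves.append(new_leaf)
    for u, v, e in sorted(t.edges()):
        e.length = float(rng.exponential(1.0))
    return t


def yule_tree(n: int, seed: int = 0) -> Tree:
    """Pure-birth binary tree: split a uniformly chosen pendant lineage until
    n leaves, then draw exponential(1) branch lengths.  Leaves are labelled
    t01..tNN; deterministic per seed."""
    if n < 2:
        raise ValidationError("yule_tree requires n >= 2")
    return _yule(n, np.random.default_rng(seed))


# -- topological perturbation ---------------------------------------------


def _random_nni(tree: Tree, rng: np.random.Generator) -> str:
    edges = list(tree.internal_edges())
    u, v, _ = edges[int(rng.integers(len(edges)))]
    b = [w for w in tree.neighbors(u) if w != v][1]
    c = [w for w in tree.neighbors(v) if w != u][int(rng.integers(2))]
    eb, ec = tree.edge(u, b), tree.edge(v, c)
    tree.remove_edge(u, b)
    tree.remove_edge(v, c)
    tree.add_edge(u, c, ec.length, ec.support)
    tree.add_edge(v, b, eb.length, eb.support)
    side = ",".join(sorted(tree.side_labels(u, v)))
    return f"nni[{side}]"


def _regraft_leaf(tree: Tree, leaf_label: str, target_label: str, rng) -> str:
    """SPR transfer: move `leaf_label`'s lineage next to `target_label`."""
    leaf = tree.node_of(leaf_label)
    target = tree.node_of(target_label)
    anchor = next(iter(tree.neighbors(leaf)))
    e_leaf = tree.edge(anchor, leaf).copy()
    tree.remove_edge(anchor, leaf)
    # anchor is internal (n >= 4 and binary), now degree 2: splice it
    (a, ea), (b, eb) = list(tree._adj[anchor].items())
    length = (ea.length or 0.0) + (eb.length or 0.0)
    tree.remove_node(anchor)
    if b not in tree._adj[a]:
        tree.add_edge(a, b, length)
    # subdivide the target's pendant edge and reattach
    tn = next(iter(tree.neighbors(target)))
    et = tree.edge(target, tn)
    tlen = et.length
    tree.remove_edge(target, tn)
    w = tree.add_node()
    half = None if tlen is None else tlen / 2.0
    tree.add_edge(tn, w, half)
    tree.add_edge(w, target, half)
    tree.add_edge(w, leaf, e_leaf.length)
    return f"spr[{leaf_label}->{target_label}]"


def _random_spr(tree: Tree, rng: np.random.Generator) -> str:
    # unconstrained SPR: move a random leaf next to another random leaf
    taxa = list(tree.taxa)
    i = int(rng.integers(len(taxa)))
    j = int(rng.integers(len(taxa) - 1))
    if j >= i:
        j += 1
    return _regraft_leaf(tree, taxa[i], taxa[j], rng)


def _perturb(
    tree: Tree,
    move: str,
    k: int,
    rng: np.random.Generator,
    hgt_pair: tuple[str, str] | None = None,
) -> tuple[Tree, tuple[str, ...]]:
    t = tree.copy()
    moves = []
    for _ in range(k):
        if move == "NNI":
            moves.append(_random_nni(t, rng))
        elif move == "SPR":
            if hgt_pair is not None:
                donor, recipient = hgt_pair
                moves.append(_regraft_leaf(t, recipient, donor, rng))
            else:
                moves.append(_random_spr(t, rng))
        else:
            raise ValidationError(f"unknown move: {move}")
    return t, tuple(moves)


def perturb_tree(
    tree: Tree,
    move: str = "NNI",
    k: int = 1,
    seed: int = 0,
    hgt_pair: tuple[str, str] | None = None,
) -> tuple[Tree, tuple[str, ...]]:
    """Apply k random topology moves; returns the new tree and move records.

    ``hgt_pair=(donor, recipient)`` constrains SPR to transfer the
    recipient's lineage next to the donor, emulating a directed HGT event.
    The leaf set is never changed.
    """
    if k < 0:
        raise ValidationError("k must be >= 0")
    if not tree.is_binary():
        raise ValidationError("perturbation requires a binary tree")
    return _perturb(tree, move, k, np.random.default_rng(seed), hgt_pair)


# -- dataset generation ----------------------------------------------------


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Seed-deterministic dataset of gene trees with drawn supports and truth labels."""
    rng = np.random.default_rng(config.seed)
    discordant_flags = rng.random(config.n_genes) < config.discordance_prob

    species = _yule(config.n_taxa, rng)
    if config.n_outgroups and config.outgroup_scale != 1.0:
        for lab in species.taxa[-config.n_outgroups :]:
            v = species.node_of(lab)
            e = species.edge(v, next(iter(species.neighbors(v))))
            e.length = (e.length or 1.0) * config.outgroup_scale
    species_splits = species.bipartition_set()
    smallest = min(species.taxa)
    all_taxa = frozenset(species.taxa)

    gene_trees: list[Tree] = []
    provenance: list[GeneProvenance] = []
    lo_hi, lo_lo = config.support_high, config.support_low
    for g in range(config.n_genes):
        gid = f"g{g + 1:04d}"
        kind, moves = "concordant", ()
        if discordant_flags[g]:
            if config.hgt_pairs:
                pair = config.hgt_pairs[int(rng.integers(len(config.hgt_pairs)))]
                tree, moves = _perturb(species, "SPR", 1, rng, hgt_pair=tuple(pair))
                kind = "hgt"
            else:
                tree, moves = _perturb(
                    species, "NNI", config.nni_moves_per_discordant_gene, rng
                )
                kind = "nni"
        else:
            tree = species.copy()
        # drawn supports: concordant edges high, perturbed edges low
        for u, v, e in sorted(tree.internal_edges()):
            side = tree.side_labels(u, v)
            if smallest not in side:
                side = all_taxa - side
            lo, hi = lo_hi if side in species_splits else lo_lo
            e.support = int(rng.integers(lo, hi + 1))
        if config.missing_prob > 0:
            while True:
                keep = [
                    t for t in tree.taxa if rng.random() >= config.missing_prob
                ]
                if len(keep) >= 4:
                    break
            if len(keep) < tree.n_leaves:
                tree = tree.restrict(keep)
        gene_trees.append(tree)
        provenance.append(GeneProvenance(gid, kind, moves))
    return SyntheticDataset(species, gene_trees, provenance, config)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write truth Newick, gene-tree Newick lines, provenance TSV, config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "species_tree": out / "species_tree.nwk",
        "gene_trees": out / "gene_trees.nwk",
        "provenance": out / "provenance.tsv",
        "config": out / "config.txt",
    }
    paths["species_tree"].write_text(write_newick(ds.species_tree) + "\n")
    paths["gene_trees"].write_text(
        "".join(write_newick(t) + "\n" for t in ds.gene_trees)
    )
    with open(paths["provenance"], "w") as fh:
        fh.write("gene_id\tkind\tmoves\n")
        for p in ds.provenance:
            fh.write(f"{p.gene_id}\t{p.kind}\t{';'.join(p.moves)}\n")
    with open(paths["config"], "w") as fh:
        for k, v in asdict(ds.config).items():
            fh.write(f"{k}={v}\n")
    return paths
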