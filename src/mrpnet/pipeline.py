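"""End-to-end orchestration: gene trees -> matrix -> NJ + network + supertree.

One call reads a file of Newick gene trees, builds the Baum-Ragan
pseudo-sequence matrix from well-supported bipartitions, computes
p-distances, the bootstrapped NJ tree, the Neighbor-Net split system, and
the MSSA supertree, writes every artifact to an output directory, and
returns a machine-readable report.  Identical inputs and seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import mrp, mssa, nj, nnet, treeio

logger = logging.getLogger(__name__)

__all__ = ["PipelineReport", "run_pipeline"]


@dataclass
class PipelineReport:
    n_genes: int
    n_taxa: int
    n_retained_bipartitions: int
    matrix_dims: tuple[int, int]
    per_gene_retained: dict[str, int]
    nj_support_summary: dict[str, float]
    n_nontrivial_splits: int
    n_incompatible_split_pairs: int
    mssa_score: float
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _support_summary(tree: treeio.Tree) -> dict[str, float]:
    sups = [e.support for _, _, e in tree.internal_edges() if e.support is not None]
    if not sups:
        return {"n": 0, "min": 0.0, "mean": 0.0, "max": 0.0}
    return {
        "n": len(sups),
        "min": float(min(sups)),
        "mean": float(np.mean(sups)),
        "max": float(max(sups)),
    }


def run_pipeline(
    gene_trees_path: str | Path,
    out_dir: str | Path,
    min_support: int = 70,
    replicates: int = 1000,
    seed: int = 0,
    mssa_restarts: int = 5,
    mssa_move: str = "NNI",
    mssa_mode: str = "topological",
    mssa_fit: str = "absolute",
    weight_floor: float = 1e-8,
    taxa: Sequence[str] | None = None,
) -> PipelineReport:
    """Run the full analysis; writes artifacts under ``out_dir``.

    Outputs: ``matrix.phy``, ``matrix.fasta``, ``dist.phy`` (square PHYLIP),
    ``nj_tree.nwk`` (bootstrap supports as node labels), ``splits.nex``
    (NEXUS SPLITS block), ``supertree.nwk``, ``mssa_trace.tsv``,
    ``report.json``.  On any stage failure the partially written outputs are
    removed and the exception re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str, text: str) -> Path:
        p = out / name
        p.write_text(text)
        written.append(p)
        return p

    try:
        logger.info("reading gene trees from %s", gene_trees_path)
        gene_trees = treeio.read_newick_trees(str(gene_trees_path))
        if not gene_trees:
            raise treeio.ValidationError("no gene trees in input")
        if taxa is None:
            universe: set[str] = set()
            for t in gene_trees:
                universe |= set(t.taxa)
            taxa = sorted(universe)
        else:
            taxa = sorted(taxa)

        logger.info("extracting bipartitions (support > %d)", min_support)
        matrix = mrp.build_mrp_matrix(gene_trees, taxa, min_support)
        _emit("matrix.phy", matrix.to_phylip())
        _emit("matrix.fasta", matrix.to_fasta())

        logger.info("matrix %dx%d; computing p-distances", *matrix.shape)
        dist = nj.p_distance(matrix)
        _emit("dist.phy", dist.to_phylip())

        logger.info("NJ with %d bootstrap replicates", replicates)
        nj_with_support = nj.bootstrap_nj(matrix, replicates, seed)
        _emit("nj_tree.nwk", treeio.write_newick(nj_with_support) + "\n")

        logger.info("Neighbor-Net split network")
        system = nnet.neighbor_net(dist, weight_floor)
        splits_path = out / "splits.nex"
        nnet.write_splits_nexus(system, str(splits_path))
        written.append(splits_path)

        logger.info("MSSA supertree search (%d restarts)", mssa_restarts)
        result = mssa.mssa_search(
            gene_trees,
            taxa,
            restarts=mssa_restarts,
            seed=seed,
            move=mssa_move,
            mode=mssa_mode,
            fit=mssa_fit,
        )
        _emit("supertree.nwk", treeio.write_newick(result.tree) + "\n")
        _emit(
            "mssa_trace.tsv",
            "restart\titerations\tscore\n"
            + "".join(f"{r}\t{i}\t{s:.10g}\n" for r, i, s in result.trace),
        )

        report = PipelineReport(
            n_genes=len(gene_trees),
            n_taxa=len(taxa),
            n_retained_bipartitions=matrix.shape[1],
            matrix_dims=matrix.shape,
            per_gene_retained=dict(matrix.per_gene_counts),
            nj_support_summary=_support_summary(nj_with_support),
            n_nontrivial_splits=len(system.nontrivial()),
            n_incompatible_split_pairs=len(system.incompatible_pairs()),
            mssa_score=result.score,
            params={
                "min_support": min_support,
                "replicates": replicates,
                "seed": seed,
                "mssa_restarts": mssa_restarts,
                "mssa_move": mssa_move,
                "mssa_mode": mssa_mode,
                "mssa_fit": mssa_fit,
                "weight_floor": weight_floor,
            },
        )
        _emit("report.json", report.to_json() + "\n")
        return report
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
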