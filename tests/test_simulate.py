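"""Synthetic species/gene-tree generator: shapes, determinism, provenance."""

import numpy as np
import pytest

from mrpnet import (
    ValidationError,
    build_mrp_matrix,
    parse_newick,
    read_newick_trees,
    robinson_foulds,
    write_newick,
)
from mrpnet.simulate import (
    SimulationConfig,
    generate_dataset,
    perturb_tree,
    write_dataset,
    yule_tree,
)


class TestYule:
    def test_minimal_cherry(self):
        t = yule_tree(2, seed=0)
        assert t.n_leaves == 2 and t.taxa == ("t01", "t02")

    def test_seventeen_taxa_edge_count(self):
        t = yule_tree(17, seed=1)
        assert t.is_binary()
        assert sum(1 for _ in t.internal_edges()) == 17 - 3

    def test_seed_determinism(self):
        assert write_newick(yule_tree(10, seed=5)) == write_newick(yule_tree(10, seed=5))
        assert write_newick(yule_tree(10, seed=5)) != write_newick(yule_tree(10, seed=6))

    def test_positive_lengths(self):
        t = yule_tree(9, seed=3)
        assert all(e.length > 0 for _, _, e in t.edges())

    def test_n_below_two_raises(self):
        with pytest.raises(ValidationError):
            yule_tree(1)


class TestPerturb:
    def test_zero_moves_identity(self):
        t = yule_tree(8, seed=2)
        p, moves = perturb_tree(t, "NNI", 0, seed=0)
        assert robinson_foulds(t, p) == 0 and moves == ()

    @pytest.mark.parametrize("seed", range(6))
    def test_single_nni_changes_exactly_one_split(self, seed):
        t = yule_tree(10, seed=seed)
        p, moves = perturb_tree(t, "NNI", 1, seed=seed)
        assert robinson_foulds(t, p) == 2 and len(moves) == 1

    def test_leafset_never_changes(self):
        t = yule_tree(9, seed=7)
        for move, k in [("NNI", 3), ("SPR", 2)]:
            p, _ = perturb_tree(t, move, k, seed=1)
            assert p.taxa == t.taxa and p.is_binary()

    def test_hgt_regraft_places_recipient_next_to_donor(self):
        t = yule_tree(10, seed=4)
        donor, recipient = "t01", "t09"
        p, _ = perturb_tree(t, "SPR", 1, seed=0, hgt_pair=(donor, recipient))
        d = p.node_of(donor)
        anchor = next(iter(p.neighbors(d)))
        cherry = {p.label(w) for w in p.neighbors(anchor) if p.is_leaf(w)}
        assert {donor, recipient} <= cherry


class TestGenerate:
    def test_counts_and_concordance(self):
        ds = generate_dataset(
            SimulationConfig(n_taxa=10, n_genes=25, discordance_prob=0.0, seed=3)
        )
        assert len(ds.gene_trees) == 25
        assert all(robinson_foulds(g, ds.species_tree) == 0 for g in ds.gene_trees)
        assert all(p.kind == "concordant" for p in ds.provenance)

    def test_discordance_flags_recomputable_from_seed(self):
        """The first n_genes uniforms of the seeded stream decide perturbation."""
        cfg = SimulationConfig(n_taxa=10, n_genes=100, discordance_prob=0.2, seed=77)
        ds = generate_dataset(cfg)
        expected = np.random.default_rng(77).random(100) < 0.2
        observed = np.array([p.kind != "concordant" for p in ds.provenance])
        assert np.array_equal(observed, expected)
        assert sum(observed) == sum(1 for g, f in zip(ds.gene_trees, expected) if f)

    def test_concordant_edges_draw_high_support(self):
        ds = generate_dataset(
            SimulationConfig(n_taxa=8, n_genes=10, discordance_prob=0.0, seed=5)
        )
        for g in ds.gene_trees:
            for _, _, e in g.internal_edges():
                assert 85 <= e.support <= 100

    def test_low_support_perturbed_edges_filtered_out(self):
        """With support_low capped at 70, perturbed splits contribute no columns."""
        cfg = SimulationConfig(
            n_taxa=10,
            n_genes=40,
            discordance_prob=0.5,
            support_low=(30, 70),
            seed=9,
        )
        ds = generate_dataset(cfg)
        m = build_mrp_matrix(ds.gene_trees, list(ds.taxa()), 70)
        truth = ds.species_tree.bipartition_set()
        for col in m.columns:
            assert col.as_canonical_set() in truth

    def test_missing_taxa(self):
        cfg = SimulationConfig(n_taxa=12, n_genes=30, missing_prob=0.2, seed=8)
        ds = generate_dataset(cfg)
        sizes = {g.n_leaves for g in ds.gene_trees}
        assert min(sizes) >= 4 and any(s < 12 for s in sizes)
        assert all(set(g.taxa) <= set(ds.taxa()) for g in ds.gene_trees)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_taxa=3)
        with pytest.raises(ValidationError):
            SimulationConfig(discordance_prob=1.5)
        with pytest.raises(ValidationError):
            SimulationConfig(support_high=(90, 80))

    def test_dataset_serialization_roundtrip(self, tmp_path):
        ds = generate_dataset(SimulationConfig(n_taxa=8, n_genes=12, seed=1))
        paths = write_dataset(ds, tmp_path)
        back = read_newick_trees(str(paths["gene_trees"]))
        assert len(back) == 12
        for orig, re in zip(ds.gene_trees, back):
            assert write_newick(orig) == write_newick(re)
        truth = parse_newick(paths["species_tree"].read_text())
        assert robinson_foulds(truth, ds.species_tree) == 0
        assert "gene_id\tkind\tmoves" in paths["provenance"].read_text()
        assert "n_taxa=8" in paths["config"].read_text()
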