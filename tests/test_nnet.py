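"""Neighbor-Net split systems: closed forms, tree fidelity, boxes, NEXUS I/O."""

import numpy as np
import pytest

from mrpnet import (
    ValidationError,
    build_mrp_matrix,
    circular_split_distance,
    neighbor_net,
    p_distance,
    path_length_matrix,
    read_splits_nexus,
    split_compatible,
    write_splits_nexus,
)
from mrpnet.distmat import DistanceMatrix
from mrpnet.nnet import Split, SplitSystem

from conftest import random_additive_tree

BOX = DistanceMatrix(
    list("ABCD"),
    np.array(
        [[0, 1, 2, 1], [1, 0, 1, 2], [2, 1, 0, 1], [1, 2, 1, 0]],
        float,
    ),
)


class TestClosedForms:
    def test_three_taxa(self):
        d = DistanceMatrix(list("ABC"), np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        s = neighbor_net(d)
        assert len(s.splits) == 3 and all(sp.is_trivial for sp in s.splits)
        w = {min(sp.side_a if len(sp.side_a) == 1 else sp.side_b): sp.weight for sp in s.splits}
        assert w == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_too_few_taxa(self):
        with pytest.raises(ValidationError):
            neighbor_net(DistanceMatrix(["A", "B"], np.zeros((2, 2))))


class TestBoxCase:
    def test_two_incompatible_unit_splits(self):
        s = neighbor_net(BOX)
        nt = s.nontrivial()
        sides = {tuple(sorted(sp.side_a)) for sp in nt}
        assert sides == {("A", "B"), ("A", "D")}
        for sp in nt:
            assert sp.weight == pytest.approx(1.0, abs=1e-6)
        x, y = nt
        assert not split_compatible(x, y)

    def test_box_distance_roundtrip(self):
        s = neighbor_net(BOX)
        rt = circular_split_distance(s).reorder(BOX.taxa)
        assert np.allclose(rt.values, BOX.values, atol=1e-9)

    def test_hand_built_box_system_distance(self):
        taxa = tuple("ABCD")
        sys = SplitSystem(
            taxa,
            ("A", "B", "C", "D"),
            [Split.from_sides("AB", "CD", 1.0), Split.from_sides("AD", "BC", 1.0)]
            + [Split.from_sides({t}, set(taxa) - {t}, 0.0) for t in taxa],
        )
        rt = circular_split_distance(sys).reorder(taxa)
        assert np.allclose(rt.values, BOX.values)

    def test_empty_and_single_split_distance(self):
        taxa = tuple("ABCD")
        empty = SplitSystem(taxa, taxa, [])
        assert np.all(circular_split_distance(empty).values == 0)
        one = SplitSystem(taxa, taxa, [Split.from_sides("AB", "CD", 2.5)])
        d = circular_split_distance(one)
        assert d.get("A", "C") == 2.5 and d.get("A", "B") == 0.0


class TestTreeFidelity:
    @pytest.mark.parametrize("n", [5, 7, 10])
    def test_additive_input_recovers_tree_splits(self, n):
        for seed in range(5):
            t = random_additive_tree(n, seed + n)
            dm = path_length_matrix(t, "branch_length")
            s = neighbor_net(dm)
            got = {tuple(sorted(sp.side_a)) for sp in s.nontrivial()}
            want = {tuple(sorted(b)) for b in t.bipartition_set()}
            assert got == want
            rt = circular_split_distance(s).reorder(dm.taxa)
            assert np.abs(rt.values - dm.values).max() < 1e-6

    def test_all_weights_nonnegative_and_circular(self):
        rng = np.random.default_rng(3)
        pts = rng.random((8, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        s = neighbor_net(DistanceMatrix([f"t{i}" for i in range(8)], D))
        for sp in s.splits:
            assert sp.weight >= 0
            assert s.is_interval(sp)  # circularity, structurally


class TestHGTSignal:
    def test_transfer_creates_boxes_implicating_the_pair(self):
        """An SPR transfer between two lineages must surface as conflicting
        splits that disagree about the donor/recipient pair's placement."""
        from mrpnet.simulate import SimulationConfig, generate_dataset

        ds0 = generate_dataset(SimulationConfig(seed=2, discordance_prob=0.0, n_genes=1))
        pm = path_length_matrix(ds0.species_tree)
        n = len(pm.taxa)
        far = max(
            ((pm.values[i, j], pm.taxa[i], pm.taxa[j]) for i in range(n) for j in range(i + 1, n)),
        )
        a, b = far[1], far[2]
        ds = generate_dataset(
            SimulationConfig(seed=2, discordance_prob=0.2, hgt_pairs=((a, b),))
        )
        m = build_mrp_matrix(ds.gene_trees, list(ds.taxa()), 70)
        s = neighbor_net(p_distance(m))
        nt = s.nontrivial()
        sep = [sp for sp in nt if sp.separates(a, b)]
        grp = [sp for sp in nt if not sp.separates(a, b)]
        conflicts = [(x, y) for x in sep for y in grp if not split_compatible(x, y)]
        assert len(conflicts) >= 1
        implicated = {frozenset(sp.side_a) for pair in conflicts for sp in pair}
        assert len(implicated) >= 2


class TestNexusIO:
    def test_counts_and_roundtrip(self, tmp_path):
        s = neighbor_net(BOX)
        assert len(s.splits) == 6  # 4 trivial + 2 box splits
        p = tmp_path / "s.nex"
        write_splits_nexus(s, str(p))
        text = p.read_text()
        assert "NSPLITS=6" in text and "CYCLE" in text
        s2 = read_splits_nexus(str(p))
        assert s2.circular_order == s.circular_order
        w1 = sorted((tuple(sorted(sp.side_a)), round(sp.weight, 6)) for sp in s.splits)
        w2 = sorted((tuple(sorted(sp.side_a)), round(sp.weight, 6)) for sp in s2.splits)
        assert w1 == w2

    def test_three_taxon_nexus(self, tmp_path):
        d = DistanceMatrix(list("ABC"), np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], float))
        p = tmp_path / "t.nex"
        write_splits_nexus(neighbor_net(d), str(p))
        assert "NTAX=3 NSPLITS=3" in p.read_text()
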