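"""Newick parsing/serialization, RF distance, and path-length matrices."""

import itertools

import numpy as np
import pytest

from mrpnet import (
    NewickError,
    ValidationError,
    parse_newick,
    path_length_matrix,
    robinson_foulds,
    write_newick,
)
from mrpnet.mssa import enumerate_topologies

from conftest import dendropy_rf, random_additive_tree


class TestParse:
    def test_star_tree(self):
        t = parse_newick("(A,B,C);")
        assert t.taxa == ("A", "B", "C")
        assert list(t.internal_edges()) == []

    def test_supports_and_lengths(self):
        t = parse_newick("((A:1,B:2)95:0.5,C:1,D:1);")
        assert t.n_leaves == 4
        ((u, v, e),) = list(t.internal_edges())
        assert e.support == 95 and e.length == 0.5
        a = t.node_of("A")
        assert t.edge(a, next(iter(t.neighbors(a)))).length == 1.0

    def test_rooted_input_is_unrooted(self):
        # degree-2 root suppressed: both quartet writings give the same tree
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("(A,B,(C,D));")
        assert robinson_foulds(t1, t2) == 0
        assert write_newick(t1) == write_newick(t2)

    @pytest.mark.parametrize(
        "bad",
        ["((A,B);", "(A,B))C;", "(A,B", "", "(A,,B);"],
    )
    def test_malformed_raises(self, bad):
        with pytest.raises(NewickError):
            parse_newick(bad)

    def test_duplicate_labels_raise(self):
        with pytest.raises(ValidationError):
            parse_newick("(A,A,B);")

    def test_out_of_range_support_raises(self):
        with pytest.raises(ValidationError):
            parse_newick("((A,B)150,C,D);")

    def test_non_numeric_internal_label_ignored(self):
        t = parse_newick("((A,B)cladeX,C,D);")
        ((_, _, e),) = list(t.internal_edges())
        assert e.support is None


class TestWrite:
    def test_canonical_child_order(self):
        assert write_newick(parse_newick("((B,A)90,C,D);")) == "((A,B)90,C,D);"
        assert write_newick(parse_newick("(C,A,B);")) == "(A,B,C);"

    def test_quoted_labels_roundtrip(self):
        t = parse_newick("('sp one','sp(2)',C);")
        assert set(t.taxa) == {"sp one", "sp(2)", "C"}
        assert parse_newick(write_newick(t)).taxa == t.taxa

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("n", [4, 7, 12])
    def test_roundtrip_preserves_everything(self, n, seed):
        t = random_additive_tree(n, seed)
        for _, _, e in t.internal_edges():
            e.support = (seed * 13 + n) % 101
        s = write_newick(t)
        t2 = parse_newick(s)
        assert robinson_foulds(t, t2) == 0
        assert write_newick(t2) == s  # idempotent
        def sup(tr):
            smallest = min(tr.taxa)
            out = []
            for u, v, e in tr.internal_edges():
                side = tr.side_labels(u, v)
                if smallest not in side:
                    side = frozenset(tr.taxa) - side
                out.append((tuple(sorted(side)), e.support))
            return sorted(out)

        assert sup(t2) == sup(t)


class TestRobinsonFoulds:
    def test_examples(self, quartet, quartet_alt):
        assert robinson_foulds(quartet, quartet) == 0
        assert robinson_foulds(quartet, quartet_alt) == 2
        assert robinson_foulds(parse_newick("(A,B,C,D);"), quartet) == 1

    def test_leafset_mismatch_raises(self, quartet):
        with pytest.raises(ValidationError):
            robinson_foulds(quartet, parse_newick("(A,B,E);"))

    def test_metric_on_all_five_taxon_topologies(self):
        trees = list(enumerate_topologies("ABCDE"))
        assert len(trees) == 15
        d = [[robinson_foulds(a, b) for b in trees] for a in trees]
        for i, j, k in itertools.product(range(15), repeat=3):
            assert d[i][j] == d[j][i]
            assert d[i][j] <= d[i][k] + d[k][j]
            assert (d[i][j] == 0) == (i == j)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_dendropy(self, seed):
        rng = np.random.default_rng(seed)
        t1 = random_additive_tree(8, seed)
        t2 = random_additive_tree(8, seed + 100)
        assert robinson_foulds(t1, t2) == dendropy_rf(t1, t2)


class TestPathLengthMatrix:
    def test_quartet_topological(self, quartet):
        pm = path_length_matrix(quartet)
        assert pm.get("A", "B") == 2 and pm.get("C", "D") == 2
        for x, y in [("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]:
            assert pm.get(x, y) == 3

    def test_branch_lengths(self):
        pm = path_length_matrix(parse_newick("((A:1,B:1):1,(C:1,D:1));"), "branch_length")
        assert pm.get("A", "C") == 3.0

    def test_missing_lengths_raise(self, quartet):
        with pytest.raises(ValidationError):
            path_length_matrix(quartet, "branch_length")

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_four_point_condition(self, n):
        for seed in range(5):
            pm = path_length_matrix(random_additive_tree(n, seed), "branch_length")
            d = pm.values
            for i, j, k, l in itertools.combinations(range(n), 4):
                sums = sorted(
                    [d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]]
                )
                assert sums[1] == pytest.approx(sums[2], abs=1e-9)
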