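import io

import dendropy
import numpy as np
import pytest

from mrpnet import parse_newick, write_newick
from mrpnet.simulate import yule_tree


@pytest.fixture
def quartet():
    return parse_newick("((A,B),(C,D));")


@pytest.fixture
def quartet_alt():
    return parse_newick("((A,C),(B,D));")


def random_additive_tree(n: int, seed: int):
    """Random binary tree with strictly positive branch lengths (exp(1) draws)."""
    return yule_tree(n, seed=seed)


def dendropy_rf(t1, t2) -> int:
    """Independent Robinson-Foulds via dendropy, from canonical Newick text."""
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(
        data=write_newick(t1), schema="newick", taxon_namespace=tns, rooting="force-unrooted"
    )
    d2 = dendropy.Tree.get(
        data=write_newick(t2), schema="newick", taxon_namespace=tns, rooting="force-unrooted"
    )
    from dendropy.calculate import treecompare

    return treecompare.symmetric_difference(d1, d2)


def dendropy_nj(dm):
    """Independent Neighbor-Joining via dendropy, returned as an mrpnet Tree."""
    buf = "x," + ",".join(dm.taxa) + "\n"
    for i, t in enumerate(dm.taxa):
        buf += t + "," + ",".join(str(x) for x in dm.values[i]) + "\n"
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(buf), delimiter=",")
    return parse_newick(pdm.nj_tree().as_string(schema="newick").replace("[&U]", "").strip())
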