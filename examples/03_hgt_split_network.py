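"""Horizontal gene transfer leaves boxes in the Neighbor-Net network.

We designate the two most distant lineages of a simulated species tree as
a donor/recipient pair and let 20% of genes carry an SPR transfer moving
the recipient's lineage next to the donor.  The resulting split network
contains incompatible split pairs that disagree about the pair: species
signal separates donor from recipient, transfer signal groups them.  Those
conflicts are the quantitative analogue of the reticulate "boxes" a
split-network viewer draws.
"""

from mrpnet import build_mrp_matrix, neighbor_net, p_distance, path_length_matrix, split_compatible
from mrpnet.simulate import SimulationConfig, generate_dataset

truth = generate_dataset(SimulationConfig(seed=3, discordance_prob=0.0, n_genes=1)).species_tree
pm = path_length_matrix(truth)
n = len(pm.taxa)
_, donor, recipient = max(
    (pm.values[i, j], pm.taxa[i], pm.taxa[j]) for i in range(n) for j in range(i + 1, n)
)
print(f"designated transfer pair: {donor} -> {recipient}")

ds = generate_dataset(
    SimulationConfig(seed=3, discordance_prob=0.2, hgt_pairs=((donor, recipient),))
)
matrix = build_mrp_matrix(ds.gene_trees, list(ds.taxa()), min_support=70)
system = neighbor_net(p_distance(matrix))

nontrivial = system.nontrivial()
sep = [s for s in nontrivial if s.separates(donor, recipient)]
grp = [s for s in nontrivial if not s.separates(donor, recipient)]
conflicts = [(x, y) for x in sep for y in grp if not split_compatible(x, y)]

print("non-trivial splits:", len(nontrivial))
print("incompatible pairs disagreeing about the transfer pair:", len(conflicts))
for x, y in conflicts[:3]:
    print("  separating:", sorted(x.side_a), f"(w={x.weight:.4f})",
          "vs grouping:", sorted(y.side_a), f"(w={y.weight:.4f})")
# Any such conflict means the data support two irreconcilable placements of
# the recipient -- vertical descent and the transfer -- at the same time.
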