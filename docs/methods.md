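# Methods

This note documents the models and numerical choices behind `mrpnet`, in
the spirit of a methods appendix: what each stage computes, which defaults
matter, what the synthetic generator does and does not emulate, and where
design decisions were genuinely open.

## Trees and bipartitions

Trees are unrooted, leaf-labelled, with optional non-negative branch
lengths and optional integer edge supports in [0, 100]. Input Newick may
be rooted; a degree-2 root is suppressed on load because every quantity
downstream is a function of the unrooted topology. Supports are read from
internal-node labels (the convention of common ML programs); non-numeric
internal labels are ignored, and edges without a support value are treated
as *unsupported*, i.e. they fail any support filter. Serialization is
canonical — children ordered by smallest descendant leaf label, written
from the internal node next to the largest leaf, branch lengths at six
significant digits — so that equal trees produce identical bytes, which in
turn makes whole-pipeline runs byte-reproducible.

Robinson–Foulds distance is the size of the symmetric difference of the
non-trivial bipartition sets (cross-checked in the test suite against
dendropy's implementation). Path-length matrices come in two modes:
`topological` (edge counts) and `branch_length` (sums); note that pruning
a tree to a taxon subset preserves branch-length distances but *not*
topological ones, which is why MSSA re-prunes per source in topological
mode.

## Matrix representation

Each gene tree contributes one matrix column per internal edge with
support strictly greater than the threshold (default 70, matching the
usual "well-supported" convention). The cell alphabet is `{A, T, ?}`:
taxa on the canonical side (the one holding the lexicographically smallest
taxon of the gene) get `A`, the rest `T`, and taxa missing from the gene
`?`. Two choices deserve emphasis:

- **Polarity is immaterial.** The p-distance treats `A` and `T`
  symmetrically, so any column could be flipped without changing any
  downstream number; the canonical rule exists purely for reproducibility
  and is asserted as an invariant in the tests.
- **Duplicates are retained.** A split recovered by k genes appears as k
  identical columns and therefore pulls the distances k times as hard.
  Deduplication would erase exactly the signal the resampling bootstrap
  needs.

The `?` convention for missing taxa is the standard matrix-representation
choice; with full-occupancy core genes (the motivating use) it never
fires.

## Distances, NJ, bootstrap

Distances between pseudo-sequences are uncorrected p-distances with
pairwise deletion: d(i,j) = mismatches / comparable columns. No
substitution correction is applied — on a symmetric two-state alphabet
whose "states" are arbitrary split sides, a correction would model noise
that is not there. A taxon pair sharing no comparable column is an error
naming the pair.

Neighbor-Joining is the standard Q-criterion agglomeration. Two details
are pinned for determinism: ties in Q are broken by the first minimum in
row-major order over the current node list (initial taxa sorted
lexicographically, joined nodes appended), and negative branch-length
estimates are clamped to zero at assignment. The 3-taxon closed form
a = (d_AB + d_AC − d_BC)/2 is used for the final join.

Bootstrap supports resample columns with replacement to the original
width, recompute distances and the NJ tree, and report for each internal
edge of the point-estimate tree the percentage of replicates containing
the same bipartition, rounded half away from zero. Replicates in which
some pair loses all comparable columns are skipped and counted, with the
percentage taken over completed replicates. Default 1000 replicates.
Implementation note: per-pair comparable/mismatch column masks are
precomputed once, so each replicate costs two matrix–vector products.

## Neighbor-Net

Phase 1 (ordering) follows the original agglomerative scheme. Clusters
hold one or two linked nodes. The cluster pair to join is chosen by the
NJ criterion on average-linkage distances; the node pair within the two
chosen clusters by the same criterion with all four candidate nodes and
the companion nodes treated as singleton clusters. Linking produces a
path of up to four nodes, reduced back to two by the standard replacement

    d(u,·) = 2/3 d(x,·) + 1/3 d(y,·)
    d(v,·) = 2/3 d(z,·) + 1/3 d(y,·)
    d(u,v) = (d(x,y) + d(x,z) + d(y,z))/3

for each consecutive triple x–y–z. All ties break by scanning order
(lexicographic taxon order), so the cycle is a deterministic function of
the matrix. The implementation was validated against the independent R
implementation in phangorn: on random Euclidean metrics both produce
identical cycles (up to rotation/reflection) and identical NNLS split
weights to six decimals.

Phase 2 (weights) solves non-negative least squares over all n(n−1)/2
interval splits of the cycle (`scipy.optimize.nnls`). Non-trivial splits
with weight ≤ `weight_floor` (default 1e-8) are dropped; trivial splits
are always reported, whatever their weight, because pendant edges are part
of the network's geometry. n = 3 is handled by the pendant closed form
directly. For additive input the fit residual is zero, the non-trivial
splits equal the source tree's bipartitions, and the weights equal its
branch lengths — the package asserts this round-trip to 1e-6.

The NEXUS output writes TAXA and SPLITS blocks (CYCLE statement plus one
weighted split per line as 1-based taxon indices in cycle order), the
dialect split-network viewers read; a reader for the same dialect enables
round-trip tests.

## MSSA

The score of a supertree T against sources S₁..Sₖ is
Σᵢ Σ_{pairs} |D(T|taxa(Sᵢ)) − D(Sᵢ)| over unordered leaf pairs, with
`topological` path lengths and absolute differences by default; squared
differences and branch-length matrices are available. The literature
leaves the exact fit flavor open; the default here is the common
path-length-on-topologies configuration, and both options are exposed
rather than asserted as canonical.

The search is steepest-descent hill climbing: evaluate the full NNI
neighborhood (2(n−3) trees; SPR optional for harder landscapes), move to
the best strictly-improving neighbor, stop at a local optimum. Restart 1
starts from the NJ tree of the sources' pseudo-sequence distances — the
informed start mirrors the pipeline's own NJ stage and, on near-concordant
data, usually starts at or next to the optimum. Later restarts (default
5 total) start from seeded random topologies. The matrix built for the
informed start applies *no* support filter (sources handed to the
supertree stage may carry no supports at all); this is the one place the
filter is deliberately bypassed. Exhaustive enumeration over all
unrooted topologies (used as the test oracle up to n = 7) lives in the
same module but shares no code with the search path.

## Synthetic data

The generator emulates the *shape* of a core-genome study, not its
sequences: a Yule (pure-birth) species tree with exponential(1) branch
lengths over 17 taxa by default, the last two taxa given 4× pendant
branches to play the role of distant outgroups; 100 gene trees by default
(scaled down from the 851 of the motivating study — full scale runs fine
but adds nothing to the properties under test). Discordance is modelled
topologically: each gene is independently perturbed with probability
`discordance_prob` (default 0.1), either by k random NNI moves (default
1) or, when donor/recipient pairs are designated, by an SPR transfer that
moves the recipient's lineage next to the donor — the topological
signature of HGT, with direct truth labels per gene.

Supports are drawn, not recomputed: edges matching a species-tree
bipartition draw uniformly from 85–100, others from 30–80. The pipeline
only ever consumes support *numbers*, so this shortcut is faithful to the
interface while keeping the generator instant. The low range deliberately
straddles the 70 threshold: roughly a fifth of perturbed edges survive
filtering, which is what lets conflict reach the network stage. The first
`n_genes` uniform draws of the seeded stream decide which genes are
perturbed, so the discordance tally can be recomputed independently from
the seed.

What passing tests on this generator do **not** show: robustness to
alignment/estimation error beyond the drawn-support model, to coalescent
(incomplete-lineage-sorting) discordance, or to systematic biases such as
compositional attraction. They show that the pipeline's inference
machinery is correct and well-behaved under topological discordance of
known structure.

## Conflict detection and the "box" signal

An HGT transfer makes the recipient cluster *with* the donor in perturbed
gene trees. In consequence, splits separating donor from recipient all
come from the (mutually compatible) species-tree chain, while every
conflict-induced split groups the pair — already visible in the 4-taxon
closed form: species split AB|CD plus transfer C→A yields exactly the box
{AB|CD, AC|BD}, whose members both separate (A,D) and (B,C) but never
both separate (A,C). The assertable analogue of "the network shows boxes
among these taxa" is therefore: the split system contains non-trivial
splits locked in pairwise-incompatible conflicts that *disagree about the
pair* — one separating donor from recipient, a conflicting one grouping
them. The tests require at least two such implicated splits in ≥ 18 of
20 seeded runs at 20% transferred genes; measured 19/20, and in those
networks every incompatible split pair implicated the designated pair.

## Problem sizes and determinism

Default test and acceptance scales — 17 taxa × 100 genes, 200 bootstrap
replicates in tests (1000 is the pipeline default), 10–20 seeded
replicates per property — were chosen so the full suite runs in well
under a minute while every property is exercised at study-like
dimensionality. Every stochastic entry point takes an explicit seed
(numpy `default_rng`); pipelines with equal inputs and seeds produce
byte-identical artifact files.

## Known limitations

- Neighbor-Net weights use ordinary (unweighted) non-negative least
  squares; no variance model for the distance estimates is applied.
- The NJ stage offers no distance corrections (by design, see above), and
  no BioNJ/weighted variants.
- MSSA search is a local optimizer; the exhaustive oracle shows 5 restarts
  suffice at small n, but hard conflict landscapes at large n may need
  SPR moves or more restarts.
- Polytomies parse and serialize but the search and perturbation
  machinery requires binary trees.
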