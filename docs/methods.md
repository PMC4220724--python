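# Methods

This note documents the models and procedures `phylocomm` implements, the
choices made where conventions diverge, and what the synthetic data do and
do not establish about behaviour on real data.

## Trees and tree surgery

Trees are rooted, with named tips and non-negative branch lengths, held as
`dendropy.Tree` objects; the root in the Newick string is taken as given
and never moved (analyses of constrained ML trees have their deep
structure fixed by the constraint, so re-rooting would be wrong). A node
with a single child never appears in any returned tree: suppressing one
sums the two incident branch lengths, which preserves all tip-to-tip path
lengths.

**Pruning.** `prune_to_tips` restricts a tree to a species subset and by
default re-roots at the most recent common ancestor (MRCA) of the retained
set, discarding the root-side stub. Consequences used throughout: the
patristic distance matrix of the retained tips is unchanged (to the few
ulps that re-ordering float additions allows), and the pruned tree's total
branch length equals Faith's PD of the subset on the original tree
(root-exclusive). `keep_root_stub=True` retains the root path as a stub
edge length on the new root for root-inclusive sums.

**Resolution.** The resolution of a tree is the number of internal edges
with length > tol divided by *n* − 2, the internal-edge count of a fully
resolved rooted binary tree on the same tips, capped at 1. The denominator
is a convention (one could count only edges actually present); *n* − 2
makes 1.0 mean "fully bifurcating with every internal branch positive",
so a binary ML tree that expresses uncertainty as zero-length branches is
penalized for them, and a polytomy and a zero-length branch score
identically. `tol` defaults to exactly 0 because parsed branch lengths
are literal text; a small positive value is available for trees that have
passed through floating-point pipelines.

**Monophyly.** A taxonomic group is monophyletic when its MRCA's
descendant tips are exactly the group. Singleton groups are trivially
monophyletic and excluded from the rate's denominator by default, since
counting them only inflates the score; a flag includes them. The rate is
invariant under branch-length rescaling by construction.

## MPL calibration

Mean path length dating assigns each internal node the age

  age(v) = mean over descendant tips t of the path length v → t,

tips age 0; each branch becomes age(parent) − age(child); all ages are
then multiplied by root_age / age(root) (root_age = 1 by default, i.e.
relative time). One postorder pass carries (tip count, summed path
length) per subtree; polytomies need no special handling. Double
precision is ample: when no negative branch arises, every tip-to-root
depth equals root_age to better than 1e-9 relative.

A branch is negative exactly when a node's mean tip depth exceeds its
parent's, which happens in strongly rate-heterogeneous regions. The
default policy (`warn`) keeps such branches and reports a count, because
silently altering branch lengths would hide a real property of the input;
`clamp` floors them at zero for downstream metrics that assume
non-negativity (the tree is then not exactly ultrametric); `error`
aborts. Chronograms written with negative branches can be re-read with
`read_newick(..., allow_negative=True)`.

## Diversity metrics

All metrics are presence/absence weighted (incidence data; abundance
weighting is out of scope).

- **PD** — total branch length of the minimal connected subtree spanning
  the community. Computed from a tip × edge incidence matrix: an edge is
  in the spanning subtree iff the number of community tips below it is in
  [1, k − 1]; edges with all k tips below form the root path, added only
  under `include_root=True`. The default is root-exclusive so that
  "PD of a plot on the mega-tree" and "total length of the plot's pruned
  tree" are the same number.
- **MPD** — mean patristic distance over all unordered pairs; dominated by
  deep divergences.
- **MNTD** — mean over species of the distance to its nearest co-occurring
  neighbor; tracks shallow structure; MNTD ≤ MPD always.
- **comdist / comdistnt** — the between-community analogues: comdist is
  the mean over the full |A| × |B| cross grid (species shared by both
  communities contribute zero-distance pairs, so comdist(X, X) > 0 in
  general), comdistnt pools the |A| + |B| nearest-cross-neighbor
  distances from both directions (a one-direction flag exists), so
  comdistnt(X, X) = 0.

Patristic distances are computed in one postorder pass that fills each
pair's entry at its MRCA; the matrix is computed once per analysis and
shared across plots.

Per-plot beta-diversity summaries use the n − 1 off-diagonal contrasts of
a plot: mean, interquartile range (linear-interpolation quantiles) and a
95% CI, by default the normal approximation mean ± 1.96 · sd/√m over the
m contrasts (a percentile option exists). The diagonal is stored but
never summarized.

## Null model

The *taxa.labels* null shuffles species names uniformly across tips while
the tree and the incidence matrix are untouched, so every replicate
preserves each plot's richness and each species' plot occupancy. Only
species that occur somewhere in the community data enter the shuffle;
tips absent from every plot keep their identity. One permutation per
replicate serves all plots, preserving cross-plot structure within a
replicate, and the permutation stream depends only on the seed and the
species pool — never on the metric — so SES values for different metrics
run with the same seed are paired.

Ranking uses the +1 convention with half-weight ties:
obs_rank = 1 + #(null < obs) + ½ #(null = obs),
p_low = obs_rank / (nreps + 1). Ties are real, not hypothetical: PD on
trees with many zero-length branches produces exact ties. Classification:
clustered if p_low < α, overdispersed if p_low > 1 − α, else random —
i.e. one-sided rank p read off both tails. A null distribution with zero
spread (e.g. a plot containing every shuffled species) is flagged
degenerate with SES = 0 rather than dividing by zero; the sd threshold is
relative (1e-12) because permuted summation order can leave femto-scale
jitter in an otherwise constant null.

Important consequence of the data-restricted shuffle pool: a community
matrix whose species do not span the tree randomizes only within the
covered pool. The power analyses therefore pair a focal structured plot
with its complement plot so that the pool is the whole tree, which is
also how a multi-plot study behaves (the pooled plots cover the
mega-phylogeny).

## Comparison pipeline

Resolution is measured on the raw trees, before calibration — MPL
averaging generically destroys zero-length internal branches, so any
other order would erase the quantity being compared. Diversity metrics
are measured on MPL chronograms.

Both members of each comparison are put on the same relative-time scale:
the mega-side estimate for a plot is the plot's subtree pruned from the
mega-phylogeny (topology and branch lengths inherited from the shared
tree) and then MPL-calibrated to root age 1, exactly as the individually
built tree is. This makes the comparison a pure function of the trees'
disagreement: identical inputs give a percent difference of exactly 0 for
every metric. The percent difference is 100 · (M_i − M_j)/M_j with i =
individual-tree estimate and j = mega-tree estimate; it is undefined when
the mega-side estimate is 0.

Spearman correlations use mid-ranks for ties (Pearson correlation of the
rank vectors). The two-sided p-value is an exact permutation enumeration
for n ≤ 10 (evaluated in vectorized chunks) and the asymptotic
t-approximation for larger n; a constant input leaves ρ undefined and is
flagged rather than guessed. Latitude enters correlations as |latitude|
by default — the gradient of interest is distance from the equator —
with a signed option.

## Synthetic data

The generator is the package's model of the study system, not a test
fixture:

- **Mega-tree**: pure-birth (Yule) tree. Two lineages from the root; at k
  lineages the next split waits Exponential(k · λ) and hits a uniformly
  chosen lineage; one final Exponential(n · λ) stretch brings all tips to
  the present. Ultrametric and binary by construction. Pure birth rather
  than birth–death because extinction adds nothing the downstream
  analyses are sensitive to.
- **Reconstruction error**: every branch times an independent
  lognormal(0, σ) factor, then an exact fraction of internal edges set to
  0. Defaults σ = 0.25 (a plausible branch-length estimation error for
  short barcode alignments) and zero-edge fraction 0.22, chosen so a
  simulated mega-tree has resolution ≈ 0.78 like a large constrained ML
  barcode tree.
- **Communities**: random = uniform k-subset; clustered = uniform anchor
  plus its k − 1 nearest tips by patristic distance (deterministic,
  ties by label; an exp(−d/τ) sampling kernel is available for softer
  clustering); overdispersed = greedy max–min spacing seeded with the two
  most distant tips. Deterministic variants are the default because their
  expected signatures are sharp and testable.
- **Study scale**: defaults are 1347 species and 15 plots with richness
  (337, 326, 192, 146, 141, 129, 98, 62, 54, 42, 30, 28, 18, 7, 7),
  the scale of the multi-plot forest study this pipeline is built for.
  Synthetic latitude rises as richness falls (rank-based, with N(0, 2°)
  jitter), emulating the latitudinal diversity gradient so correlation
  stages have signal.

What the simulations do **not** emulate: phylogenetic signal in habitat
preference across plots, spatially structured species pools, non-random
taxon sampling of the barcode data, alignment/model misspecification
biases (the branch noise is i.i.d., real error is not), or abundance
structure. Passing tests therefore demonstrate correctness of the
computations and the expected qualitative behaviour of the metrics under
controlled assembly processes — not that any particular empirical system
will show those effects.

A known quantitative property of the assembly regimes: greedy max–min
assembly maximizes nearest-neighbor spacing, so its signature is extreme
in SES(MNTD) (essentially always significant at the sizes exercised) but
only moderate in SES(MPD) — random subsets of a Yule tree already span
most deep splits, so max–min communities clear the null's 95th MPD
percentile in only roughly four of five replicates at n = 200, k = 20.
Clustered (nearest-k) assembly is the mirror case, with its strongest
signature in MNTD.

## Problem sizes and numerics

The test suite and the acceptance script run everything at or below the
default study scale; the largest single objects are the 1347 × 1347
patristic matrix (~15 MB) and 999-permutation null streams, kept
vectorized in numpy. Brute-force oracle comparisons (edge marking,
explicit double loops) are exact to 1e-12 on trees of ≤ 12 tips.
Chronogram ultrametricity is asserted at 1e-9 relative; pruning-distance
preservation at 1e-12 relative (bit-exactness is impossible once branch
sums re-associate). Tie-breaks anywhere an order could matter
(community assembly, label iteration) are lexicographic on labels, and
every stochastic operation takes an explicit seed or generator.

## Limitations

- No unrooted-tree semantics; input trees must be rooted as intended.
- No abundance-weighted metrics, UniFrac/PhyloSor variants, alternative
  null models (richness, independentswap, …) or spatially explicit nulls.
- No tree inference or dating beyond MPL; no fossil or calendar-time
  calibration.
- `comdist`'s self-comparison and shared-species conventions follow the
  literal all-cross-pairs definition; studies with site-disjoint species
  lists are unaffected, overlapping communities should mind the
  zero-distance contributions.
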