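# Methods

This note documents the models, conventions and numerical choices behind
`simplicia`, in the spirit of a methods appendix: what each component assumes,
which knobs matter, and what the synthetic generator does and does not emulate.

## Connectome representation

A connectome is a directed simple graph over a validated neuron table
(id, soma position in μm, synapse class E/I, optional cell-type and
proofreading labels) with integer edge weights equal to aggregated synapse
counts. Conventions:

- Duplicate neuron ids are treated as segmentation mergers: *all* rows sharing
  a duplicated id are dropped, not just the surplus ones.
- Self-loop synapse rows and rows whose endpoints are missing from the neuron
  table are discarded (drop counts kept in `meta`).
- Reciprocal connections are two independent directed edges; autapses are
  excluded (simplices require distinct nodes in any case).
- Coordinates are micrometres throughout; readers can convert voxel indices at
  a 4 × 4 × 40 nm pitch.
- The HDF5 container stores the node table plus CSR arrays (indptr, indices,
  weights) with fixed dtypes and no timestamps, so re-serialization of a loaded
  file is byte-identical; a format-version attribute guards compatibility.

Subvolume selection mirrors standard practice for EM subnetworks: a 5 × 3 grid
of 500 × 300 μm rectangles shifted by 50 μm (overlapping), half-open bounds
[min, max) on the two horizontal axes so a shift-equals-width grid tiles the
volume exactly once, the vertical axis unbounded. Excitatory membership is
restricted to the rectangle; interneurons are admitted regardless of position
(an optional margin supports conventions where the inhibitory rectangle is
enlarged on all four sides).

## Directed flag complex

Enumeration recursively extends ordered cliques by the intersection of the
out-neighborhoods of all current members; this lists each directed simplex
exactly once and needs only the adjacency structure. Reciprocally connected
pairs contribute one simplex per valid ordering (standard directed flag
complex semantics). Enumeration is intended for the excitatory subgraph; the
caller passes the subgraph explicitly. Counting (`count_simplices`) shares the
recursion without materializing lists; listing above dimension 10 requires an
explicit opt-in as a memory guard.

The reconstruction-error control inverts the expected maximal dimension
≈ −2 log(n)/log(p) of an undirected ER graph: solving for p at a target
dimension gives the directed edge budget n(n−1)p, from which the removal
fraction to reach an observed edge count follows. The survival probability of
one specific d-simplex under independent edge recall r is r^C(d+1, 2) — the
number of edges in the motif (28 for d = 7).

The triad census enumerates weakly-connected triples exactly (edge-anchored
enumeration), classifies a uniform sample when the total exceeds the sample
budget, and scales class frequencies linearly by the exact total.

## Inhibition relative to simplices

The tensors M_ei / M_ie are stored sparse in simplex-major layout; their
position sums M′ feed the disynaptic matrix I = M′_ei · M′_ie^T. Two
deliberate choices:

- **Synapse counts by default.** I counts synapse-weighted E→I→E paths; a
  `binarize` flag switches to 0/1 connections, since either convention is
  defensible and both appear in practice.
- **Off-diagonal statistics.** The symmetry score 𝕊 = var(I − I^T)/var(I) and
  the overlap–inhibition Pearson correlations use off-diagonal entries only:
  the diagonal of I − I^T is identically zero and the diagonal of I measures
  self-inhibition, not between-simplex inhibition. Variances are population
  variances. 𝕊 = 0 for symmetric I; for entrywise-independent (i,j)/(j,i) the
  expectation is 2. Note 𝕊 on the column-shuffle control concentrates at 2
  only when per-simplex totals are homogeneous; with strongly heterogeneous
  row masses the control sits below 2, which is why data and control are
  always reported together.

The column-shuffle null permutes the interneuron columns of M′_ei and M′_ie
with two *independent* uniform permutations (independence is the weaker, safer
null; per-simplex inhibitory in/out totals are preserved either way).

The inhibitory-targeting test uses the hypergeometric survival function with
population = pooled interneuron outdegree, successes = pooled outdegree onto
interneurons, and draws = the neuron's own total outdegree. The printed form
of such tests sometimes leaves the draw count implicit; drawing d_j^ttl slots
is the reading consistent with a null that "keeps the total outdegrees of
individual neurons", and d_inh = 0 yields p = 1 as required. The default
threshold is 1e−6, chosen to flag roughly the disinhibitory-class fraction
(~15% of interneurons).

Overlap between simplices within a position range [j, k] is plain set
intersection, order-agnostic inside the range. For low target dimensions the
pipeline narrows the canonical source side (positions 0–2) and target side
(d−2..d) so the two ranges never share a position — sharing a position would
conflate source- and target-side effects.

## Grouping, neighborhoods, rewiring

Louvain clustering runs on the overlap matrix with zeroed diagonal
(self-overlap is not affinity) at resolution 2.2, seeded; restarts keep the
best-modularity partition; labels are relabeled contiguously by smallest
member for determinism. The group-level network reports mean any-position
overlap (excitation) and the fraction of cross pairs whose disynaptic
inhibition exceeds the per-pair 95th percentile of the shuffle ensemble
(inhibition); a pooled-percentile option exists for small shuffle budgets —
per-pair is the stricter default.

Neighborhood complexity compares the induced subgraph on a node plus all its
afferents and efferents against the same node's neighborhood in a
configuration-model control (directed double-edge swaps, 10 accepted swaps per
edge, rejecting self-loops and multi-edges; degree sequences preserved
exactly). The degree flavor inside the neighborhood is total (in + out) degree
by default, configurable to in or out. The two degree samples have equal size
by construction, so the 1-Wasserstein distance reduces to the mean absolute
difference of sorted samples; unequal sizes fall back to the general quantile
integral. One control instance per run by default; averaging over several
instances is supported.

A rewiring step removes m edges whose maximal simplex dimension is ≤ D
(uniformly at random) and adds m edges between currently unconnected ordered
pairs with probability proportional to
Σ_{dim>D} Σ_{i<j∈pos} Par[dim,i](a)·Par[dim,j](b), pos = {0, 1} by default
(source-side placement). Participation counts and edge dimensions are computed
once on the pre-step graph; pairs vacated by this step's removals are eligible
for addition (they are unconnected at addition time); additions are sampled
without replacement by sequential draws with renormalization. Edge count and
node set are conserved exactly. The reference schedule is one step at
(D=3, m=2000) followed by three at (D=2, m=10000); the synthetic default is
scaled to the generator's graph sizes.

## The synthetic generator

The generator produces the conditions the analyses assume, not a facsimile of
any EM dataset:

- **Soma cloud.** Uniform positions in a rectangular slab; default 400 E + 80 I
  in 400 μm³ — large enough for thousands of background edges yet cheap enough
  that the full chain runs in seconds.
- **Distance-dependent background.** Independent Bernoulli connections per
  ordered pair with P(d) = a·exp(−d/b) per E/I pathway (defaults a = 0.03,
  b = 150 μm; the model is implemented as a *decaying* exponential — a growing
  exponential cannot be a probability at large d). Synapse counts default to
  1 per connection, with a geometric-distribution option for heavier tails.
- **Planted divergence.** 25 motifs of dimension 5. Each position p draws from
  its own disjoint pool of m_p nodes, m_p interpolating linearly from the
  source-pool size (10) at p = 0 to the motif count at p = d, assigned
  round-robin. The number of distinct neurons per position is therefore exact
  and strictly increasing — a deterministic skeleton for the divergence
  analyses, at the cost of not modeling the fluctuations a stochastic reuse
  process would show. Planting only adds missing edges (graphs stay simple and
  planting is idempotent).
- **Position-biased inhibition.** Each neuron in a planted simplex gets a mean
  normalized position p̄ over its occurrences; E→I edges are sampled once per
  (neuron, interneuron) pair with probability rising toward the source
  (1 + in_bias·(1−p̄)) and I→E toward the target (1 + out_bias·p̄). Sampling
  per pair rather than per simplex occurrence keeps binarized degree profiles
  monotone despite heavy source reuse. A loop-back motif — interneurons excited
  by a simplex's source side innervate that simplex's target side — couples
  disynaptic inhibition to source-side overlap, the structure behind the
  overlap–inhibition correlations.
- **Disinhibitory class.** A configured fraction of interneurons (default
  planted at 0.15 in the recovery fixtures) wires onto other interneurons at
  high rate, biased toward the interneurons most engaged with simplices, on
  top of a low flat I→I baseline from the rest — so targeting-test recovery and
  the rising share of disinhibition with simplex degree are both measurable.
- **Activity.** A joint Gaussian with target pairwise correlation
  corr_profile[max edge dimension] for connected pairs (0 otherwise), shifted
  per node to be nonnegative (shifts leave Pearson correlations unchanged).
  If the assembled target matrix is not PSD it is projected onto the PSD cone
  with a warning (or raises, configurable). Feasibility is the user's
  responsibility for dense graphs with large correlations.

What passing the synthetic recoveries does *not* show: the generator has no
morphology, no layers, no cell-type-specific connectivity beyond the planted
biases, uniform rather than laminar soma densities, and its divergence
skeleton is deterministic. Results on real connectomes additionally face
proofreading artifacts and edge effects that the stratified variants and
subvolume conventions only partially address.

## Pipeline and sizes

`run_analysis` seeds every stage from one root seed through SeedSequence
spawns; identical configs give identical manifests (content hashes recorded
per stage). The runner analyzes the full synthetic slab — equivalent to a
one-cell subvolume grid; grid-based selection and mean ± SD aggregation over
subnetworks are available as library functions. Default problem sizes (480
neurons, ~4.5k edges, ~25 simplices at the target dimension, 20 shuffles, 50
complexity nodes) keep a full run under a second; the analytic ER benchmark at
n = 14,559, m = 819,869 enumerates up to dimension 4 in a few seconds.

Tie-breaks and degenerate inputs: target-dimension selection breaks ties
toward the lower dimension (smaller motifs, the conservative choice);
all-zero overlap matrices cluster as singletons with a warning; constant
matrices yield NaN statistics with warnings rather than errors; z-scoring with
degenerate spread returns zeros.
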