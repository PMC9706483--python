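# Methods

## Problem setting

An interactome is modelled as an undirected simple graph over opaque string
gene identifiers. Confidence scores, when present in the input edge list,
are applied once as a cutoff filter (e.g. keep edges with score ≥ 0.8) and
kept as edge metadata; every algorithmic step afterwards uses the
unweighted topology. This matches the random-walk formulation below, which
is defined on the row-normalized binary adjacency matrix; a weighted
row-normalization mode exists behind `RWRParams(weighted=True)` but is off
by default.

Seed genes pass through an explicit, visible pipeline: raw identifiers →
optional many-to-one ID mapping (collisions are deduplicated and reported,
never silently resolved) → *mapped* seeds present in the network →
*connectable* seeds lying in the network component used for module
building. All reported recovery rates are relative to connectable seeds.

## Random walk with restart

The walker follows `p(t+1) = (1 − r) Wᵀ p(t) + r p0` with `W` the
row-normalized adjacency (the mass leaving node *i* splits equally over its
neighbours — the only reading under which "flow" through a connector is
meaningful and total mass is conserved) and `p0` the 0/1 seed indicator.

* `r = 0.75` by default: the walk stays local to the seeds, with a
  geometric convergence rate of `1 − r` per iteration.
* `p0` is deliberately left unnormalized. Only the induced ranking is used
  downstream and the fixed point is linear in `p0`, so normalization is a
  pure rescaling; `normalize_restart=True` applies it when calibrated
  probabilities are wanted.
* Convergence: L1 change below `1e-10` or 10 000 iterations, whichever
  comes first (both configurable). Non-convergence is flagged on the
  result, not raised, since a truncated iterate still ranks.
* Isolated nodes are rejected: a degree-0 node has no outgoing
  distribution. The TOPAS driver avoids this by running the walk on the
  preprocessed network (the interactome's largest connected component),
  which is also where candidate connectors are searched.

The iterative fixed point equals the direct solve
`p = r (I − (1−r) Wᵀ)⁻¹ p0`; the test suite checks agreement to 1e-8 on
random graphs against a dense linear-algebra oracle.

## TOPAS

`d` counts the connectors allowed between two seeds, so the seed–seed hop
budget is `d + 1` edges. Values above 3 are allowed but warned against:
long paths recruit functionally unrelated genes.

Candidate pool: strict shortest-path membership by default
(`dist(s,v) + dist(v,t) = dist(s,t) ≤ d+1`), computed by truncated BFS from
each seed. The relaxed alternative (`dist(s,v) + dist(v,t) ≤ d+1`,
admitting detours no longer than the budget) is a config flag
(`on_shortest_paths_only=False`); both semantics are reasonable readings of
"on a shortest path of bounded length" and the strict one is the default
because it yields the smaller, more conservative pool.

Pruning is a single pass over the pool in **ascending** RWR probability:
low-flow candidates are tested (and usually removed) first, so the
high-flow connectors are the ones left holding the module together. The
direction is the single most consequential free choice in the method and is
therefore isolated in one function (`rank_candidates`); reversing the sort
there flips the policy. "Component count unaltered" is implemented as exact
equality. A removal can never silently isolate a surviving candidate: every
pool member starts with degree ≥ 1 inside `G_s` (its shortest-path
neighbours are seeds or fellow candidates), and a removal that would
strand a neighbour increases the component count and is rejected.
Consequences asserted in tests: the seed component partition is invariant
under pruning, every retained connector is cut-critical in the final
module, and pruning is idempotent. No re-ranking happens after removals —
the walk is computed once on the preprocessed network, not per step.

Ties anywhere (equal probabilities, equal component sizes) break
lexicographically on node IDs, making every run bit-reproducible. All
computations are serial; determinism is the contract, and no thread count
affects any result.

## Baselines

All three share one hypergeometric connectivity test: for a node of degree
`k` with `ks` links to the `s` seeds among `N` network nodes, the upper-tail
probability of ≥ `ks` seed links when `k` neighbours are drawn from the
`N − 1` other nodes. The universe excludes the evaluated node itself; the
choice is made once, in one function, so DIAMOnD and MaxLink remain mutually
consistent. The p-value is computed in exact integer arithmetic
(`math.comb`), which is both deterministic and free of tail cancellation.

* **DIAMOnD**: 200 rounds by default; each round scores every neighbour of
  the current cluster (cluster counts as seeds) and admits the lowest
  p-value. Ties: higher seed-link count, lower degree, then ID. The
  high-degree down-weighting hyperparameter is fixed at its null
  contribution (α = 1) and deliberately not exposed.
* **MaxLink**: candidates are first neighbours of seeds, scored by seed-link
  count, retained at p < 0.05, ranked by link count, then p, then ID.
* **SCA**: fixed pool of seed first-neighbours; greedily add whichever
  candidate most increases the LCC size of the growing subnetwork (ties:
  seed-link count to the current members, then ID); stop at no improvement.
  Note that under this objective any candidate adjacent to the current LCC
  improves it by one node, so SCA absorbs every pool member reachable from
  the growing component; its connector counts on dense neighbourhoods are
  correspondingly larger than TOPAS's.

For evaluation parity, every method's prediction is reduced to its largest
connected component by a shared post-processing step before scoring.

## Degree-aware permutation tests

The null model draws random gene sets matched to the observed degree
distribution: nodes are sorted by degree and cut into equal-occupancy bins
of ~100 nodes (configurable); each template gene is replaced by a uniform
draw from its bin, without replacement within a sample, falling back to the
nearest non-empty bin when one is exhausted. Template genes may re-enter
the sample — excluding them would bias the null upward for well-connected
sets.

Empirical p-values use `(1 + #{null ≥ observed}) / (1 + n)`, so `p = 0` is
impossible and the test remains valid at any `n`. Both statistics in use
(LCC size; Jaccard index of term sets) are discrete, so these p-values are
conservative: their null distribution is a step function that undershoots
the uniform by the largest tie mass, and a naive uniformity check would
reject it. `randomize_ties=True` splits the tie mass with a uniform draw —
the standard randomized permutation p-value, exactly Uniform(0, 1] under
the null — and is what the calibration tests exercise; reported results use
the conservative default. Defaults follow the study convention of 10 000
samples; tests and the acceptance script use 150–1 000 samples, which is
ample for the effect sizes involved.

Pathway relevance: within each cluster of a supplied module partition
(e.g. an Infomap run; the partition is an input, clustering is out of
scope), the observed statistic is the Jaccard index between the term sets
annotating seed members and connector members; the null resamples connector
members degree-aware. Clusters with an unannotated side are reported as
untestable and excluded from the Benjamini–Hochberg correction rather than
assigned p = 1, so they cannot dilute the FDR. BH adjustment delegates to
statsmodels; an independent step-up implementation backs it in the tests.

## Synthetic study conditions

`generate_scale_free` is Barabási–Albert preferential attachment, giving
connected graphs with `m(n − m)` edges and right-skewed degrees
(mean > median), the qualitative signature of real interactomes. The
default suite — 100 instances of 2 000 nodes at `m = 3` (mean degree ≈ 6,
comparable to confidence-thresholded functional networks), 20 seeds, 8
hidden connectors, `d = 2` — is the standard study condition used by the
tests and (at 30 instances) by the acceptance script.

`plant_module` wires the planted structure by *adding* edges: the hidden
connectors form a clique and seeds attach round-robin, one hidden connector
each (all-to-all at `d = 1`; a seed clique when no hidden connectors are
requested). Adding edges, rather than hunting for a pre-existing subgraph,
is the only way to guarantee the planted invariant — every seed pair joined
through at most `d` intermediate hidden connectors — in an arbitrary
scale-free graph; the perturbation is ≤ `C(n_hidden, 2) + n_seeds` edges on
a 6 000-edge network. The invariant implies every seed pair sits within
`d + 1` hops of each other in the full network too, so all shortest-path
intermediates are pool members and the top-down search must recover all
seeds in one component: SRR = 1 is ground truth, not an empirical
observation. Hidden-connector recall is *not* guaranteed — the surrounding
network legitimately offers alternative shortest paths, and occasionally
one with higher walker flow displaces a planted connector — which is why
the recovery contract asks for mean recall ≥ 0.8 rather than 1.

What the generator does not emulate: confidence-score distributions of
specific databases, assortativity and clustering of real interactomes,
heterogeneous seed sets spanning several components, and annotation
structure. Passing on these fixtures therefore demonstrates algorithmic
correctness and the advertised invariants, not biological performance on
real disease gene sets.

## Degenerate inputs and numerical choices

Edgeless networks are legal everywhere and yield empty results rather than
errors; a single seed yields an empty candidate pool and a seed-only
module. Readers report malformed rows with line numbers; unknown node IDs
passed to subgraph operations are dropped with a log line. Component
orderings are by size descending then smallest member ID; all RNG use flows
through explicit integer seeds (per-instance seeds derived from a master
seed by fixed offsets), never global state.

## Known limitations

* Preprocessing keeps only the network's largest component; seeds in minor
  components are reported as unconnectable rather than processed as
  separate sub-problems.
* The pruning order (ascending flow) and the equality component test are
  policy choices among readings that the method description leaves open;
  both are isolated behind single functions and config flags.
* Module clustering (Infomap) is consumed as an input partition, not
  computed.
* The prize-collecting-Steiner-tree family of top-down methods is out of
  scope, as are downloads of any real interactome; the edge-list readers
  accept them when the user supplies the files.
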