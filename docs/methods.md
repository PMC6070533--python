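# Methods

## The problem

Genes associated with a disease cluster into *modules* of the protein
interaction network, and diseases with similar phenotypes have overlapping
modules. Given an undirected interactome `G` and two incomplete seed sets
`a ⊂ A` and `b ⊂ B` (the known members of two overlapping modules), the task
is to predict which nodes of `G` belong to `A ∩ B`. The same machinery
applies to any pair of network modules — functional modules, context-specific
subnetworks — not only disease modules.

## The S2B score

For a node `k`, double specific betweenness is the fraction of *retained*
shortest paths linking the two seed sets that pass through `k`:

    S2B(k) = Σ_{i∈a, j∈b} sp(k,i,j) · t(i,j)  /  Σ_{i∈a, j∈b} t(i,j)

with two indicator functions computed from hop distances `d(·,·)`:

* `sp(k,i,j) = 1` iff `d(i,j) = d(i,k) + d(k,j)` — for unweighted graphs this
  is exactly "`k` lies on at least one shortest path from `i` to `j`";
* `t(i,j) = 1` iff `d(i,j) ≤ avgd(G)`, the average shortest-path length of
  the network over connected node pairs. This drops seed pairs that are
  farther apart than a typical node pair, whose connecting paths say little
  about the module overlap.

Seeds present in both raw sets are, by definition, already in the overlap;
they are discarded before scoring (and reported separately). Pairs whose
endpoints include `k` itself are excluded from both sums for that `k`: the
identity makes `sp ≡ 1` at an endpoint, and excluding both endpoints (rather
than only the `b`-side one) is what keeps the score invariant under swapping
the two seed sets — a property the test suite verifies. Non-shared seeds are
still scored; a seed of one module is a legitimate candidate for the other.
Disconnected pairs contribute to neither sum; a node with denominator 0
scores 0 so the ranking stays total.

The implementation runs one BFS per seed (via `scipy.sparse.csgraph`) and
evaluates the additivity test vectorially over all nodes; per-pair shortest
path *sets* are only ever materialized in the test oracle, which enumerates
them explicitly with networkx and must agree exactly.

## Threshold and specificity

Scores are heavily right-skewed: plotting `S2B` against `1 − quantile(S2B)`
gives an L-shaped curve. The threshold `S2B_t` is the observed score closest
to the origin of that curve,

    S2B_t = argmin_s  (s / max S2B)² + (1 − quantile(s))²,

where `quantile(s)` is the empirical fraction of scored nodes with score
≤ `s` (zeros included — they shape the L), ties broken toward the smaller
score. Candidate selection uses a strict `score > S2B_t`.

Two specificity scores control for generic centrality, each computed from
`n_random = 200` randomizations by default, every randomization contributing
to all nodes simultaneously:

* **SS1** — probability the real score meets or exceeds the score under
  *random seed sets* of the same sizes, drawn uniformly (without
  replacement, forced disjoint) from all network nodes;
* **SS2** — probability the real score meets or exceeds the score on a
  *degree-preserving rewired network* (double-edge swaps, 10×|E| attempted
  swaps; `avgd` is recomputed on each rewired graph, since the length filter
  is a property of the graph in which paths are traced).

Both use `≥`, so a graph that cannot be rewired (a star) yields SS2 = 1
everywhere. Default candidate filter: `S2B > S2B_t` and both SS > 0.90.

## DIAMOnD baseline

The comparison method expands a single seed set by *connectivity
significance*: at each of 250 iterations, every node adjacent to the current
module is scored with the hypergeometric tail probability of having at least
its observed number of links into the module given its degree, the module
size and the network size; the smallest p-value joins. Ties are broken
toward higher degree, then lexicographic identifier (the reference algorithm
leaves ties to the implementation). The two-disease protocol runs the
expansion separately from each seed set and intersects the two added-node
lists; that intersection is DIAMOnD's overlap prediction. Matched precision
then compares, per module pair, the DIAMOnD intersection against the same
number of top-ranked S2B nodes.

## Artificial module benchmark

Because real interactomes and disease-gene lists are versioned external
resources, the validation suite is fully synthetic:

* **Base network** — Barabási–Albert preferential attachment, default 5,000
  nodes at mean degree 8 (m = 4), node ids `n0000`…; a scaled-down surrogate
  for a literature interactome (ours is roughly 40% of the node count of a
  merged literature/screen network, with a comparable density but, like any
  pure preferential-attachment graph, essentially no clustering — see
  *Limitations*).
* **shell modules** — the start node plus successive BFS shells, the last
  shell randomly subsampled to hit a target size drawn uniformly in
  [200, 400]. Earlier shells are complete, so every subsampled node keeps a
  parent and the module is connected.
* **conn modules** — grown from a single start with the same hypergeometric
  criterion DIAMOnD predicts with, to a fixed size of 250; ties broken at
  random so two modules from nearby starts are not forced onto identical
  trajectories.
* **rwr modules** — random walk with restart at the start node (restart
  probability 0.5; stationary distribution solved directly from the sparse
  linear system, LU-factorized once per network). Nodes are admitted in
  decreasing visit score among neighbors of the growing module, which equals
  the plain top-250 whenever the top-250 set is connected and guarantees a
  connected module otherwise.
* **Pairs** — the second module starts at a uniformly drawn member of the
  first and the pair is rejected until the overlap size lands in [50, 125]
  (up to `max_tries`, failures logged and skipped).
* **Seeds** — a uniform 50% sample of each module by default; robustness
  experiments replace a fraction of sampled seeds with random non-members
  (contamination), lower the seed fraction, or rewire a fraction of the
  network edges before scoring (modules stay defined on the original graph).

Per-pair metrics: precision / neighbor-precision / recall as a function of
S2B rank (indicator series smoothed with a centered moving average of width
3; recall never smoothed so it stays monotone), top-20 precision, top-3
hits, and DIAMOnD-matched precision. Rankings exclude only the discarded
shared seeds — single-set seeds remain, as in the real-data protocol.
Pairs with an empty DIAMOnD intersection have undefined matched precision
and are excluded from medians. Summary tables report median and quartiles
(linear-interpolation convention). Specificity filtering is off by default
in benchmarks: module pairs are selected only by overlap size, not hub
content, so the filters are not needed to make the comparison fair, and
skipping them keeps 150 pairs tractable.

## Candidate subnetwork analysis

For a real candidate set the package reports (i) all maximal cliques of
size ≥ 4 in the candidate-induced subgraph (Bron–Kerbosch via networkx,
verified against an exhaustive oracle in tests), and (ii) clusters of
candidates that co-occur on the retained shortest paths: for every seed pair
passing the `t` filter, all shortest paths are enumerated (capped at 100 per
pair, cap hits logged) and every unordered candidate pair sharing a path is
counted. Candidates are then clustered by average-linkage hierarchical
clustering on distance `1 − count / max(count)`; the cut is chosen by mean
silhouette over k = 2..10 unless a k is given. The co-occurrence
normalization and clustering method are this package's choice — the
procedure is deliberately pluggable.

## Numerical and design choices

* Distances are exact BFS hop counts; `avgd` is exact up to 2,000 nodes and
  otherwise a Monte-Carlo estimate over 100,000 uniformly sampled ordered
  pairs (BFS rows computed for the unique sources). Disconnected pairs are
  excluded throughout — the only convention compatible with a finite `t`
  threshold.
* All randomness flows through numpy Generators seeded from a single global
  seed; per-stage substreams are derived by hashing `seed:stage-name`, so
  adding a stage never perturbs earlier stages' draws. Identical seeds give
  byte-identical outputs; rankings break score ties lexicographically.
* Hypergeometric tails come from `scipy.stats.hypergeom.sf`, deduplicated
  per iteration over distinct (links-in, degree) pairs.
* Node identifiers are opaque case-sensitive strings; no symbol mapping.

## Limitations

* The surrogate network has the degree heterogeneity of an interactome but
  not its clustering or community structure: pure preferential attachment
  has vanishing clustering coefficient, so shortest paths concentrate on
  hubs more than in a real protein network, and both S2B and DIAMOnD see a
  harder, more hub-confounded problem than on real data. Benchmarks run
  here measure the method under those conditions; absolute precision values
  on real interactomes can differ in either direction, and the published
  real-network behavior (very small DIAMOnD two-run intersections, near-
  perfect top-rank S2B precision on shell-type modules) is only partially
  reproduced at this scale.
* The three module generators are reconstructions from their names and the
  stated size/overlap constraints; the original generation scripts are not
  public in detail.
* Weighted or directed graphs are out of scope, as is any gene-identifier
  normalization or enrichment analysis downstream of the candidate list.
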