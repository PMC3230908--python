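# Methods

## Problem and model

An interactome is modeled as an undirected simple graph `G(V, E)`: nodes are
proteins, edges are reported pairwise interactions. Reported edges are a
mixture of physiological interactions and detection artifacts, with
high-throughput experiments contributing most of the false positives. The
package's pipeline is: (1) map each edge to a confidence weight in [0, 1];
(2) cluster the weighted graph into candidate complexes; (3) score the
candidates against a reference catalog. Self-interactions are dropped on
input and pairs are unordered throughout, so all downstream formulations
operate on simple graphs.

## Evidence model

Raw input is one record per (protein pair, experiment) observation, each
carrying an opaque experiment identifier and a detection-method category.
Aggregation per unordered pair yields the quantities the evidence-based
schemes consume:

- `Ne` — the number of distinct experiments reporting the pair (duplicate
  records of the same pair and experiment count once);
- the **plurality** of each reporting experiment — the number of distinct
  pairs that experiment reports across the *whole* input. Plurality is a
  throughput proxy: a plurality-1 experiment targeted exactly this
  interaction, a plurality-5000 screen reported it among thousands.
  Pluralities are recomputed from the supplied records so the tool is
  self-contained; a column of precomputed pluralities (as exported by
  aggregated databases) can be read instead via `ColumnConfig(plurality=...)`.
- the set of distinct detection-method categories.

Experiment identifiers are treated as opaque units; whether they denote
publications or individual assays is a property of the upstream data, not of
this package.

## Weighting schemes

**MV.** `w = Ne^α / (Ne^α + A(p_1..p_Ne) − 1)`, with aggregator
`A ∈ {min, mean}` (default `min`) and boost `α > 0` (default 2). The chosen
algebraic form realizes four required properties: monotone increasing in
`Ne` at fixed pluralities; monotone decreasing in each plurality; exactly 1
when `A = 1` (a dedicated small-scale experiment certifies the edge); and
independent of `α` at `Ne = 1`, so the boost only redistributes confidence
among multi-experiment edges. `min` is the default aggregator because a
single low-plurality corroboration is the decisive reliability signal; the
formula lives in one pure function so an alternative algebraic variant with
the same properties can be swapped in without touching callers.

**Simple.** A deliberately naive baseline: `Ne = 1` scores 0.2 when the
plurality is at or above the high-throughput cutoff (default 100, a
configurable and admittedly round boundary between small-scale and screen)
and 0.9 below it; `Ne ≥ 2` lands in [0.7, 1.0], interpolated log-linearly in
the aggregated plurality (`A = 1` → 1.0, `A ≥ cutoff` → 0.7, clamped). The
interpolation shape within the band is a free design choice; log-linear was
picked because pluralities span orders of magnitude.

**ETW.** 0.2 / 0.6 / 1.0 for one / two / three-or-more distinct
detection-method categories. Categories are accepted as arbitrary labels;
any ontology coarsening is left to the data producer.

**CD-distance.** With closed neighborhoods `Int(x) = {x} ∪ N(x)`,
`w = 1 − (|Int u| + |Int v| − 2|Int u ∩ Int v|) / (|Int u| + |Int v|)` —
the Dice coefficient of the closed neighborhoods. Closed neighborhoods mean
an isolated dyad scores 1 rather than 0/0.

**Adjust-CD.** First iteration
`w¹(u,v) = 2|N_u ∩ N_v| / (|N_u| + λ_u + |N_v| + λ_v)` with penalty
`λ_x = max(0, n_avg − |N_x|)`, `n_avg` the mean neighbor-set size; the
penalty keeps sparsely characterized proteins from acquiring spuriously
high scores. Iteration `k > 1` replaces set sizes by sums of `w^{k−1}` over
the same (original) neighbor sets, with penalties recomputed from weighted
degrees. Defaults: `k = 2`, open neighborhoods (`include_self = False`);
closed-neighborhood semantics are available as an option. The score is
defined for any pair sharing a neighbor, so it can propose edges absent from
the input; these are emitted (flagged `predicted`) only behind an explicit
flag, keeping scheme comparisons on a common edge set. Zero-weight pairs are
always omitted — including original edges whose endpoints share no
neighbor, which the score genuinely judges unsupported.

## Clustering

**MCL.** The flow matrix is built from edge weights plus per-node self-loops
equal to the maximum incident weight (standard practice; stabilizes
attractors — the choice matters little on weighted graphs but prevents
period-2 oscillation on bipartite-ish structures). Iterations alternate
expansion (matrix power, default 2), inflation (entrywise power `r = 2`,
column renormalization) and pruning of entries below 1e−5, until the
maximum entry change falls below 1e−6 or 100 iterations. Clusters are the
attractor systems of the limit matrix (attractors = nodes with positive
diagonal mass, grouped by mutual support); each node joins the system
receiving its largest incoming mass, ties resolved toward the
lexicographically smallest system, making the output deterministic.
Non-convergence returns the current clustering with a warning flag in
`meta` rather than raising.

**CMC.** Maximal cliques (Bron–Kerbosch via networkx) of size ≥ 2 are ranked
by weighted density `Σ w_internal / (n(n−1)/2)`, ties by size then member
order. Walking down the ranking, a clique overlapping a kept cluster by
≥ 50% of its own size is merged into it when the interconnectivity — the
mean weight over all pairs between the clique's non-shared part and the
cluster — reaches 0.25, and discarded otherwise; cliques clearing no kept
cluster found new clusters. Output clusters may overlap. The thresholds
follow the algorithm's original formulation; both are configurable.

**Spectral.** Symmetric normalized Laplacian `L = I − D^{−1/2} W D^{−1/2}`
of the full (possibly disconnected) graph; `k` = index of the largest gap in
the ascending eigenvalue sequence (eigengap heuristic, search capped at
`k_max = 200`); embedding = the first `k` eigenvectors, rows normalized to
unit length (zero rows of isolated nodes left at zero). Points are then
clustered by k-means++ (30 independent restarts, minimum within-cluster SSE
wins) or by a diagonal-covariance Gaussian-mixture EM with k-means++
initialization and hard maximum-posterior assignment, variances floored at
1e−6 so components of identical points remain well-posed. No per-component
splitting is done before the eigendecomposition; disconnected structure is
carried by the spectrum itself.

All randomness flows from one integer seed (default 17). k-means++ restarts
draw child seeds from a generator seeded with it, so runs are exactly
reproducible; the k-means and mixture fits themselves are delegated to
scikit-learn.

## Evaluation

From the contingency matrix `T_ij = |complex_i ∩ cluster_j|`:
`Sn = Σ_i max_j T_ij / Σ_i N_i` (N_i the full complex size),
`PPV = Σ_j max_i T_ij / Σ_j T_·j`, `Accuracy = √(Sn · PPV)`. Clusters
sharing no protein with the catalog are charged into the PPV denominator
with weight equal to their size (zero numerator): without this, inventing
junk clusters would be free. `junk_clusters="ignore"` restores the
unpenalized variant for sensitivity analyses. The prediction rate counts
clusters whose overlap score `ω(P, C) = |P∩C|² / (|P||C|)` reaches 0.2
against some complex; the threshold is the conventional one and is a
config key, since matching criteria vary across studies. Clusters and
complexes below two members are excluded before scoring, consistent with
the catalog reader.

## Synthetic benchmark

`generate_graph` plants `n_complexes = 20` complexes with sizes uniform on
3–12 on disjoint protein sets, wires each internal pair with probability
`p_within = 0.9`, adds 40 edge-less background proteins, and draws noise
edges uniformly from pairs not inside any single complex until they make up
`noise_edge_fraction = 0.3` of all edges (the realized count is within one
edge of the target by construction). `simulate_evidence` then runs 2
high-throughput experiments, each reporting a Poisson(150) uniform sample
of *all* edges, and 150 small-scale experiments, each reporting every true
edge independently with probability 0.01 and, by default, no noise edges
(`small_noise_contamination` relaxes this for harder benchmarks). Edges left
unreported are attributed to one high-throughput experiment so every edge
carries evidence. Method categories: high-throughput experiments draw from
{Y2H, MS}, small-scale from {purified-complex, in-vitro, in-vivo}.

These rates were chosen so that the simulated evidence reproduces the two
qualitative features of aggregated interactome data that the evidence-based
schemes rely on: single-experiment edges form the majority (the realized
fraction is ≈0.55–0.61 across seeds), and only true edges accumulate
corroborating small-scale reports, so mean MV weight separates true
(≈0.4) from noise (≈0.005) edges. What the generator does **not** emulate:
overlapping complexes, scale-free background degree structure, correlated
experiment coverage, and systematic (non-uniform) false-positive biases of
specific technologies. Passing tests therefore demonstrate that the
pipeline exploits plurality/corroboration structure correctly, not that it
attains any particular performance level on a real interactome.

Benchmark problem sizes (20 complexes, ≈220 proteins, ≈1000 edges, 10 seeds
for distributional claims, 5 for recovery claims) keep every experiment
comfortably reproducible on a laptop while leaving enough edges for the
noise fraction and skew statistics to be stable.

## Numerical and degenerate-input choices

- Weighted degrees of zero (isolated nodes): columns normalized against a
  unit self-loop in MCL; zero embedding rows in spectral clustering; such
  nodes end up in singleton clusters and are dropped (counted in `meta`).
- Weight round-tripping through files is at 6-decimal precision; readers
  reject weights outside [0, 1] with the offending line number.
- Adjust-CD divides only where the denominator is positive and clips to
  [0, 1] against floating drift.
- Ties: MCL attractor assignment and eigengap selection break toward the
  smallest index; CMC ranking breaks by size then lexicographic member
  order. All outputs are sorted before writing, so identical seeds give
  byte-identical files.

## Known limitations

- CMC on large dense graphs can enumerate exponentially many cliques; no
  pivot-limit safeguard is installed beyond the `min_clique_size` floor.
- The eigengap heuristic under-segments graphs whose complexes overlap or
  differ greatly in internal density; `k_max` caps but does not repair this.
- Hard EM assignment discards posterior uncertainty; soft complex
  membership is out of scope.
- RNSC- and COACH-style clusterers, GO-similarity weighting and database
  redundancy removal are deliberately not implemented.
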