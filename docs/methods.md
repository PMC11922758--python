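# Methods

This note documents the models and procedures implemented in `hypoatlas`,
the assumptions behind them, the parameters that matter, and what the
synthetic benchmarks do and do not demonstrate.

## Consensus clustering and the cluster tree

**Ensembles.** A single kNN graph (Euclidean metric, undirected union of
neighbour sets, default `k_neighbors = 15`) is built per resolution from the
integrated embedding, and Leiden (RB-configuration quality) is run `n_runs`
times with seeds `base_seed + r`.  The default of 20 runs keeps desk-scale
experiments fast; production atlases typically use 100, available via
configuration.  The graph parameters are deliberately per-layer: on strongly
separated data the kNN graph is disconnected at the finest cluster scale, and
no Leiden resolution can merge disconnected components (merging always lowers
the RB quality).  Coarse layers therefore need neighbourhoods larger than one
fine cluster — the packaged recipes use `k ≈ 1.25 × cells-per-fine-cluster`
for the coarse layer.  On real, continuous data this matters less, but it is
what makes multi-scale structure visible to a graph method at all.

**HBGF consensus.** Runs are merged by the hybrid bipartite graph
formulation: cells and (run, cluster) pairs are the two vertex sets of an
incidence matrix `B`; the normalized matrix `D₁^-½ B D₂^-½` is factorized and
cells are k-means partitioned in the top-k left singular subspace
(row-normalized).  `k` defaults to the median per-run cluster count.  Two
numerical choices:

* the SVD is computed densely (LAPACK) up to 4,096 run-clusters.  Sparse
  ARPACK iteration is only used beyond that: the leading singular values of
  these matrices are highly degenerate (one per well-separated cluster), and
  ARPACK's behaviour on degenerate subspaces is not reproducible across
  calls, which would break the package's determinism guarantees;
* the k-means solution is polished by a greedy sequential local search on the
  co-association objective (cell i moves to the block c maximizing
  Σ_{j∈c}(2C_ij − 1), where C_ij is the fraction of runs co-clustering i and
  j), sweeping until a fixed point.  On small problems (≤ 512 cells) the
  search restarts from up to eight of the ensemble's own columns and keeps
  the best solution.  The refinement optimizes exactly the pairwise-agreement
  score that the package's exhaustive small-ensemble oracle measures, so
  benchmark results pin the objective rather than one solver trajectory.

**Tree reconciliation.** Flat consensus layers ordered coarse→fine are
reconciled bottom-up: each fine cluster attaches to the coarse cluster
holding the plurality of its cells (ties to the lexicographically smallest
label), and the minority cells are relabeled along the majority path.  One
bottom-up pass already yields strict nestedness; the pass is repeated to a
fixed point (bounded at 50 iterations) and the number of changed cell labels
is reported as `reconciliation_cost`.  Levels are named `C0` (coarsest)
upward, with a virtual root above `C0`.

**Pruning.** For `n_iterations = 5` passes, every node that (a) has fewer
than `min_cells = 50` cells, (b) derives more than
`max_single_donor_fraction = 90%` of its cells from one donor, or (c) has
fewer than `min_strong_markers = 5` strong markers against its siblings, is
merged into the sibling with the smallest Euclidean centroid distance.
Failing nodes are processed smallest-first (ties by node id) so the least
reliable nodes merge before they can attract others; centroids update as
weighted means on merge, and markers are recomputed each iteration.  "Strong
marker" is defined as Bonferroni-adjusted p < 0.05 *and* log₂ fold-change
≥ 0.5 versus siblings — the sibling contrast is what pruning must justify,
and the effect-size floor prevents huge-n trivial significance; both
thresholds are configurable.  Nodes without siblings are never pruned.  All
merges are recorded in `prune_log` (node, reasons, candidate distances,
target) so the merge policy is externally auditable.

## Batch-stratified marker test

Markers use a van Elteren-style stratified Wilcoxon rank-sum test.  Within
each batch s the rank-sum `W_s` of the target cells is centred at its null
mean and the strata are combined as `T = Σ_s (W_s − E_s)/(n_s+1)` with
variance `Σ_s Var(W_s)/(n_s+1)²` (tie-corrected), giving a two-sided normal
p value.  Strata missing either group are dropped; if all are dropped the
call fails loudly.  Bonferroni correction is over all genes tested.  Log
fold-changes use a 10⁻⁹ pseudocount on group means of raw counts;
detection-rate difference is the difference in nonzero fractions.

Calibration: under a two-batch null with multiplicative log-normal batch
effects (10,000 genes, 200+200 cells) the measured raw false-positive rate at
α = 0.05 is within 0.05 ± 0.01.  Against a within-stratum permutation oracle
(10,000 permutations) the normal-approximation p agrees to within Monte-Carlo
error plus ≈ 0.01; the residual allowance is the price of the normal
approximation under heavy ties at 50 cells per side, and shrinks with n.

## Cross-species cluster matching

Homology tables are reduced to a 1:1 gene map by admitting pairs greedily in
decreasing similarity order (ties broken lexicographically), so every gene
keeps only its best partner.  Shared HVGs are the intersection of each
species' top `hvg_per_species = 2,500` genes ranked by the number of
samples/batches flagging them (boundary ties resolved by mean variance when
supplied, then gene id).

Cluster centroids (mean embedding vectors) are compared across species by
Pearson correlation over embedding dimensions.  Because every cluster has
*some* best match, raw correlations are penalized relative to the best
value in their row and column: the adjusted value is `min(2r − M_row,
2r − M_col)` — an entry that is the maximum of both its row and column is
unchanged, anything else is pushed down by its gap to the better candidate.
Using the minimum of the two orientations makes the subsequent 0.7 gate
symmetric in the species; one-sided variants are available
(`mode="row"|"col"`).  Edges with adjusted correlation strictly above 0.7
form the match graph; all clusters appear as nodes so unmatched clusters are
first-class results.

The graph is then pruned to remove M:N structure: visiting nodes in
deterministic (species, id) order, any node with a neighbour of degree ≥ 2
keeps only its maximum-adjusted-correlation edge; sweeps repeat to a fixed
point (a single-pass mode exists).  The fixed point guarantees every
connected component is a star — a hub of either species with exclusive
partners — typed 1:1, 1:N (hub in species A) or M:1 (hub in species B).
Order matters in rare symmetric configurations; the deterministic visit
order makes results reproducible, and the property tests compare against an
independent re-implementation of the same rule.

## Spatial region assignment

Spots are clustered on their cluster-abundance vectors (one column per
transcriptomic cluster, z-scored per column by default so abundant cell
types do not dominate the metric; raw mode by flag) with kNN + Leiden.
Signature genes for deconvolution references are filtered by detection:
kept if expressed in ≥ 8% of cells, or rescued if expressed in ≥ 0.05% of
cells with a nonzero mean above 1.4.

For cluster c and region r: `mean_cr` is the mean spot abundance, `adj_cr`
subtracts the median across regions of c's regional means (a per-cluster
centring that zeroes ubiquitous clusters), and `mad_x = adj / MAD` where MAD
is the raw (unscaled — no 1.4826 consistency factor) median absolute
deviation of c's spot abundances within r, floored at 10⁻⁶ × the global mean
abundance to keep zero-variance regions finite (floored rows are flagged).
A cluster is assigned to its arg-max-adj region only when that region's
mad_x strictly exceeds 10; otherwise NA.  Manual overrides are applied last
and logged, never silently.  Child clusters inherit their parent's
assignment via `propagate_assignments`.

A consequence of the mad_x definition worth knowing: with Gaussian spot
noise of standard deviation σ, mad_x concentrates near
`(signal − baseline)/(0.6745 σ)` as the number of spots grows, so the
`mad_x > 10` rule can only fire when σ is below roughly 13% of the
cluster's regional abundance contrast.  Deconvolution posterior means are
typically far smoother than that (the worked example in the tests implies
≈ 4%), but noisy abundance maps will produce NA assignments by design
rather than low-confidence ones.

## GWAS effector genes

Specificity matrices are aggregated by bootstrap: `n_subsets = 10` random
subsets of `subset_size = 100,000` cells (without replacement within a
subset; independent across subsets by default, disjoint partitioning by
flag), the pluggable specificity function applied to each, and the
elementwise mean taken; genes or cell types absent from a subset contribute
zero with a warning.  The built-in default specificity is the normalized
mean expression (cell-type mean over the sum of cell-type means per gene),
which is linear enough that the bootstrap mean reproduces the full-data
value within sampling error; CELLEX-style ESμ scores plug in unchanged.

Effector genes must strictly exceed the 95th percentile of their cell
type's *nonzero* specificity values (per cell type by default, global by
flag; linear-interpolation percentile) in at least one cell type, and carry
an association rank ≤ 1,000.  Cell-type and burden significance are plain
Bonferroni gates (p < α/n, strict).

## Synthetic data: what it emulates, and what it does not

The generators produce the *shapes* the pipeline consumes with planted,
machine-readable truth:

* **Hierarchy** — Gaussian blobs around recursively placed centroids.
  Sibling centroids at the finest level are exactly `separation` apart
  (placed on randomly oriented regular simplexes), and spacing triples per
  coarser level so cousins can never approach siblings.  Defaults: 200
  cells/leaf, 10 embedding dimensions, separation/noise = 8, four donors,
  two batches.  Optional donor imbalance plants donor-dominated leaves.
* **Counts** — Gamma-Poisson with log-normal gene means (`base_mean` 0.5,
  dispersion 0.3), log-normal per-cell depth (sd 0.3) and per-(batch, gene)
  factors (`batch_effect_sd` 0.2); each leaf gets dedicated marker genes at
  10× mean.  This matches the overdispersion assumptions of rank-based
  tests without claiming to model library chemistry, ambient RNA or
  zero-inflation.
* **Species pair** — shared clusters have standard-normal centroids in a
  joint 50-dimensional embedding; the partner species' centroid adds
  isotropic noise with `divergence_sd = 0.4843`, chosen so the true-pair
  centroid correlation is 1/√(1+sd²) ≈ 0.9; private clusters are
  independent.
* **Spatial** — spot abundance = the spot's region affinity + Gaussian
  noise (clipped at 0).  The default `noise_sd = 0.5` on a signal of 10
  (5%) reflects the smoothness of deconvolution posterior means — the same
  noise scale the mad_x worked example implies.  Flat-affinity clusters are
  planted as NA truth.  No geometry is simulated: regions are memberships,
  not shapes.
* **GWAS tables** — planted effectors receive specificity 0.9–1.0 in one to
  three cell types over a ≤ 0.8 background (so they clear any per-type 95th
  percentile) and ranks within the top 1,000; the remaining top ranks go to
  zero-specificity genes so every non-planted gene fails at least one
  criterion by construction.

All generators are pure functions of their spec including the seed.
Passing benchmarks on these data demonstrates that the algorithms recover
planted structure under the stated noise models; it does not demonstrate
robustness to real-data pathologies (ambient contamination, continuous
trajectories rather than blobs, segmentation errors in spatial data,
LD-driven rank instability in gene associations).

## Known limitations

* The consensus solver is heuristic beyond the small-problem regime where
  the exhaustive oracle certifies it; the refinement guarantees a local
  optimum of the co-association objective, not the global one.
* Tree reconciliation assumes the layer order given is coarse→fine; layers
  with non-monotone granularity are reconciled but may empty coarse
  clusters.
* The mad_x rule is intentionally conservative under noisy abundance maps
  (see above); thresholds other than 10 are a caller decision.
* `bootstrap_specificity` holds one subset's count matrix in memory at a
  time; very large atlases should use the disjoint-partition mode to bound
  the number of draws.
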