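# Methods

## The model

`morphgw` treats each cell as a *metric-measure space*: a set of `n` points
sampled from the cell's reconstruction, a pairwise distance `d_i` between
those points, and uniform weight `1/n` on each point. Morphological
dissimilarity between cells `i` and `j` is the squared-loss
Gromov-Wasserstein (GW) objective

    GW(d_i, d_j) = 1/2 min_T Σ_{αβγδ} | d_i(α,β) − d_j(γ,δ) |²  T_{αγ} T_{βδ}

minimized over couplings `T ≥ 0` with row marginals `1/n_i` and column
marginals `1/n_j`. The coupling is a soft matching of points across the two
cells; the objective charges a matched pair of point pairs by how much their
within-cell distances disagree, so the optimum measures the physical
deformation needed to carry one shape onto the other. Because the input is
the *intracellular* distance matrix, the construction is invariant to
rotations, translations and reflections by construction — no pre-alignment
is ever performed.

We report `sqrt(objective)` as the distance (the GW₂ convention, under which
identity, symmetry and the triangle inequality hold); the raw objective is
kept alongside. Marginals are uniform because points are sampled evenly;
non-uniform weights are accepted but not default.

### Choice of intracellular metric

* **Euclidean** — straight-line distances between sampled points. Sensitive
  to the spatial arrangement of appendages (e.g. where dendrites point).
* **Geodesic** — shortest-path length along the skeleton (SWC trees) or the
  surface (meshes). Exactly invariant under bending at articulation points,
  hence driven by branching topology rather than pose.

Both satisfy the metric axioms; the test suite asserts symmetry, zero
diagonal and the triangle inequality to 1e-9 relative on fixtures.

## Sampling cells to n points

*SWC trees* are walked depth-first from the soma, accumulating arclength
along every root-to-leaf path and emitting a point whenever the distance
since the last emitted point on that path reaches a fixed step; the residual
is carried across branch points so the scheme is invariant under edge
subdivision. The step size giving exactly `n` points is found by bisection
(64 iterations; the count is non-increasing in the step, ties resolved to
the largest step). The soma is always the first point. Perfectly symmetric
trees can make some counts unreachable (arms emit in pairs); the sampler
reports this instead of silently returning fewer points. A seeded
uniform-by-arclength random sampler is provided for comparison.

*Meshes* are sampled by evenly spaced vertex indices
(`round(k(V−1)/(n−1))`), exploiting the fact that mesh vertices are stored
roughly ordered by spatial proximity; meshes with fewer than `n` vertices
are rejected. *2D masks* are reduced to their closed boundary contour
(Moore neighbour tracing from the top-left boundary pixel, clockwise) and
sampled at equal perimeter arclength.

Geodesics on SWC samples use the walk structure: each sample is linked to
its predecessor along the walk (edge weight = arclength between them) and
all-pairs shortest paths are computed by Dijkstra from every node — the
result equals a Floyd–Warshall evaluation but scales better. Mesh geodesics
default to shortest paths on the edge graph weighted by edge length, an
upper bound on true surface geodesics (on a subdivision-3 icosphere the
overshoot against the analytic great circle is ~6%); an exact backend can
be substituted behind the same contract.

## The solver

The GW objective with fixed marginals decomposes as
`E(T) = cA + cB − ⟨d_A T d_B, T⟩` with constants `cA, cB`; the gradient is
`−2 d_A T d_B`. We minimize by conditional gradient (Frank–Wolfe): the
linearized subproblem is a transportation LP — solved by the Hungarian
algorithm for uniform equal-size marginals, by exact atom-splitting to
`lcm(n,m)` plus assignment for uniform unequal sizes, and by HiGHS
otherwise — followed by an exact line search on the quadratic. Iteration
stops at a 1e-9 relative objective change or 1000 iterations.

The problem is non-convex, so the solve is repeated from several
deterministic starts and the best local optimum is kept:

* the product coupling `p qᵀ`;
* an alignment of points sorted by weighted row sums (a 1D eccentricity
  proxy);
* an *annealed entropic* start: mirror-descent steps with Sinkhorn
  projections at a decreasing, scale-aware temperature (fractions 0.5, 0.2,
  0.08, 0.03 of the mean-distance product), which tracks the smoothed
  problem toward the true objective and reliably escapes the saddles and
  poor basins of the product start;
* for tiny instances (`n·m ≤ 256`), a batch of random starts drawn from a
  fixed constant seed, so results remain fully deterministic.

All starts and LP tie-breaks are deterministic, so repeated runs are
bit-identical and the pairwise computation is independent of the worker
count. Results are local optima, i.e. upper bounds on the true GW value; on
tiny instances (2–4 points) the solver is validated against a brute-force
oracle (permutation enumeration plus 10⁴ projected-gradient-refined random
couplings plus constrained local polish) and agrees to ~1e-11. At the
package's default study scale the computed distance matrices show no
triangle-inequality violation above 1e-4 relative; a violation beyond that
level would indicate a solver regression, since exact GW₂ is a metric.

An entropically regularized variant (`gw_entropic`) runs mirror descent at
a fixed temperature; it approaches the unregularized value as the
regularizer shrinks and raises a diagnostic on numerical underflow. Its
iteration is deterministic; the `seed` argument exists only for interface
compatibility.

## Morphology-space operations

**Clustering** builds an unweighted kNN graph (`k=15` default, union of
directed edges) on the GW matrix and runs Louvain community detection
(igraph's multilevel algorithm) with a mandatory seed. **Embedding** runs
UMAP on the precomputed distances with a mandatory seed.

**Average shapes.** For a cluster 𝒳, the medoid is the member minimizing
the summed GW distance to the rest (ties to the smallest index). Every
member's coupling to the medoid is hardened to a permutation by maximum-
weight assignment (row-argmax cannot guarantee a permutation), and its
distance matrix is conjugated by that permutation so all matrices share the
medoid's point indexing. Two averages are exposed:

* `transport` — the entrywise mean of the aligned matrices, kept on the
  micrometre scale. The printed one-sided coupling-weighted sum (rows
  transported, columns left in the source indexing) is exposed separately
  as `transport_average` with both raw (mass-normalized) and
  `n`-rescaled outputs, because the one-sided form is asymmetric and off
  the micrometre scale by a factor `n`; the pipeline uses the symmetric
  two-sided (conjugation) form.
* `thresholded` — each matrix is rescaled by its minimum positive entry
  (making adjacent samples distance ~1), rounded, clipped at 2, then
  averaged: a consensus of unweighted adjacency structure.

The average is rendered by linking each point to its `k=3` most-adjacent
neighbours and taking the Dijkstra shortest-path tree rooted at the soma
sample (index 0). Edge costs are `1 − averaged adjacency` (i.e. the
thresholded average minus 1, clipped to [0, 1]), so consensus adjacency
edges cost ~0 and ties resolve by hop count; per-point confidence is the
summed averaged distance to the `k` selected neighbours (low = that part of
the shape is consistent across the cluster), with a min-max-scaled copy for
display.

## Feature association

Features are tested on a radius neighbour graph with `ε` defaulting to the
median GW distance. The Laplacian score of feature `f` is

    C = Σ_{ij} (f_i − f_j)² A_{ij} / Var(f)

over ordered pairs, with population variance (divisor `N`; the convention
is declared and tested against the quadratic form `2 fᵀLf / Var(f)`).
Low scores mean the feature is *localized*: morphological neighbours share
its value.

Significance is a one-tailed permutation test (`n_perm=1000` default,
add-one smoothing, low tail). With covariates, each replicate applies a
single shared permutation to the feature and all covariates simultaneously;
ordinary least squares with intercept regresses the feature's null scores
on the covariates' null scores, the residuals form the null distribution,
and the observed statistic is the covariate-adjusted score
`C − β₀ − Σ β_m C_cov`. Exact ties between the adjusted score and null
residuals (e.g. a feature identical to its covariate, where all residuals
vanish to round-off) are counted as non-extreme via a 1e-9 relative
tolerance, keeping such features non-significant. Benjamini–Hochberg is
applied across the tested (detection-filtered) features. Expression tables
are normalized as `log(1 + 5000 · count/cell_total)` and genes outside the
[5%, 90%) detection band are dropped.

Calibration on the synthetic conditions (40 cells, two communities, median-ε
graph): the empirical type-I error at α=0.05 over 200 null simulations sits
inside the binomial 95% band; planted community indicators at 3-SD shift are
recovered with power ≥ 0.9 at FDR < 0.05; age-driven features with a
community-skewed age covariate are significant unadjusted and fully absorbed
by adjustment.

## Evaluation statistics

* **CTS score** — per label, the ratio of the median between-group to the
  median within-group distance; the score is the mean of per-label ratios
  (the aggregation across labels is our declared reading of the
  median-based group discrimination statistic, and outputs label it as
  such). Invariant under global rescaling.
* **kNN classification** — stratified 7-fold cross-validation, `k=10`,
  majority vote over the precomputed distances, ties broken by smallest
  summed distance then label order; 10 repeats differing only in the fold
  seed; reports mean accuracy and the mean multiclass (Gorodkin) MCC of the
  pooled per-repeat confusion matrices. The binary case reduces to the
  familiar closed form and matches the one-hot Pearson correlation.
* **Modality simplex** — per modality, off-diagonal distances are logged
  and z-standardized; each cell pair gets coordinates
  `(d_M − d_T, d_T − d_E, d_E − d_M)`, closed to sum exactly to zero; pairs
  with a zero distance are skipped and counted, and a middle-98% trim is
  available for plotting exports.

## Synthetic study conditions

The generator grows a trunk from the soma plus `n_branches` side branches
from uniformly chosen nodes, with Gaussian branch lengths (mean 50 µm,
SD 10 µm), Gaussian branch angles (SD 0.6 rad) and 5 µm segments — sized so
that branch count is the dominant class signal, as in morphological-type
recovery. Feature tables plant community indicators at a configurable SD
shift, iid Gaussian nulls, and optionally age-driven features with an age
covariate (integers 1–5) that itself skews with community, making covariate
adjustment a real test rather than a no-op. Default scales are 30–40 cells
and 40–50 points per cell, chosen so the full pipeline runs in minutes on
one CPU while keeping every planted effect comfortably above the noise
floor.

What the synthetic conditions do **not** emulate: reconstruction artifacts
(broken or disconnected traces, soma segmentation errors), realistic
neurite tortuosity and diameter taper, class-dependent cable length
distributions, or count noise in expression data (features are Gaussian).
Passing tests therefore demonstrate the correctness and calibration of the
algorithms, not performance claims on any real dataset.

## Numerical choices and edge cases

* Distance-matrix text files store the upper triangle at 17 significant
  digits — lossless for float64 round trips.
* Unsorted SWC files (child before parent) are rejected by default;
  `resort=True` re-sorts topologically. Duplicate sampled points are
  allowed (zero distances) and logged.
* The GW symmetry guarantee comes from canonical orientation: the pair is
  ordered by size, then cell id, then matrix bytes before solving.
* `medoid` ties go to the smallest index; kNN-graph neighbour ties go to
  the smallest index (stable argsort).
* Zero-variance features and covariates are rejected with a distinct error
  rather than returning NaN scores.
* Masks must contain exactly one 8-connected object; multi-object and empty
  masks are rejected at load.

## Known limitations

* The solver returns local optima; all quality statements are backed by the
  oracle comparisons and metric checks above, not by global-optimality
  proofs.
* Mesh geodesics are edge-graph upper bounds, not exact polyhedral
  geodesics.
* The even sampler can fail on exactly symmetric trees (documented error).
* Louvain seeding relies on igraph's use of Python's `random` module; the
  clustering function saves and restores that RNG state around the call.
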