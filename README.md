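# morphgw

Cell morphology latent spaces from Gromov–Wasserstein distances between
intracellular distance matrices.

## The problem

Single-cell imaging produces digital reconstructions of cell shapes — SWC
skeletons of neurons, triangular surface meshes, 2D segmentation masks —
whose diversity is hard to summarize with hand-picked shape descriptors,
especially across very different cell types. `morphgw` compares cells
directly as *metric spaces*: each cell is discretized into `n` evenly
sampled points with their pairwise (Euclidean or geodesic) distance matrix
`d_i`, and two cells are compared by the squared-loss Gromov–Wasserstein
distance

```
GW(d_i, d_j) = 1/2 · min_T Σ_{αβγδ} |d_i(α,β) − d_j(γ,δ)|² T_{αγ} T_{βδ}
```

over couplings `T` with uniform marginals. The optimum measures the
physical deformation needed to turn one shape into the other and is
invariant to rotations, translations and reflections without any
pre-alignment; with the geodesic metric it is also exactly invariant to
bending. The resulting pairwise matrix is a genuine metric on cells — a
*morphology space* — on which the package provides the downstream algebra:

* Louvain clustering and seeded 2D UMAP embeddings;
* medoid and *average shapes* per cluster (couplings re-index every member
  onto the medoid; the averaged matrix is rendered as a k=3 nearest
  neighbour shortest-path tree with per-point confidence);
* Laplacian-score association of per-cell features (genes,
  electrophysiology, mutation indicators) with the space, using
  covariate-adjusted permutation nulls and Benjamini–Hochberg correction;
* evaluation statistics: cell-type separation (CTS) score, cross-validated
  kNN classification (accuracy, multiclass MCC), and cross-modality
  2-simplex coordinates.

It is aimed at quantitative cell biologists and neuroscientists analysing
single-cell morphology data (patch-clamp / Patch-seq reconstructions,
EM-derived meshes, segmentation masks) from Python.

## Worked example

`examples/01_build_morphology_space.py` generates two planted morphological
classes (2-branch vs 8-branch neurons, 12 cells each), samples 50 points
per cell, computes geodesic matrices and the pairwise GW space, then
clusters and embeds it:

```
24 cells; median GW distance 25.28 um (deformation cost between typical cell shapes)
Louvain clusters: 2; agreement with the planted classes (ARI) = 1.00 (1.0 = classes perfectly recovered)
2D embedding computed; per-axis spread = 6.60, 3.16 (cells with similar branching lie close together)
```

The median GW distance is the typical deformation cost (in micrometres,
since distances enter in micrometres) between cells of different branching
classes; an adjusted Rand index of 1.0 means unsupervised clustering of the
space recovers the planted classes exactly. The other scripts in
`examples/` walk through average shapes, feature association with a
confounding age covariate, the evaluation statistics, and mask/mesh inputs.

A thin CLI mirrors the batch steps
(`morphgw validate|sample|gw|cluster|associate`); seeded runs are
bit-reproducible across worker counts.

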