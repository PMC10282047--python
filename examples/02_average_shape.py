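"""Compute the medoid and average shape of a cluster of similar neurons.

Ten noisy copies of a Y-shaped neuron are averaged: couplings to the medoid
re-index every cell's geodesic matrix, the thresholded matrices are
averaged, and the k=3 nearest-neighbour shortest-path tree renders the
consensus skeleton.
"""

import numpy as np

import morphgw as mg
from morphgw.synthetic import NeuronClassSpec, generate_neuron

# ten similar cells: same growth parameters, different noise seeds
trees = [generate_neuron(NeuronClassSpec(
    n_branches=1, branch_length_mean=40.0, branch_length_sd=2.0,
    branch_angle_sd=0.4, seed=s)) for s in range(10)]

n = 40
cells = [mg.geodesic_matrix_swc(t, mg.sample_swc_even(t, n, cell_id=f"y{i}"))
         for i, t in enumerate(trees)]
space = mg.gw_pairwise(cells, store_couplings=True)

subset = list(range(10))
med = mg.medoid(space, subset)
print(f"medoid cell: {space.cell_ids[med]} "
      "(the member closest on average to the rest of the cluster)")

couplings = []
for i in subset:
    if i == med:
        couplings.append(np.eye(n) / n)
    else:
        a, b = min(i, med), max(i, med)
        T = space.couplings[(a, b)]
        couplings.append(T.T if i < med else T)

shape = mg.build_average_shape(space, subset, [c.D for c in cells], couplings)
deg = np.bincount(shape.spt_edges.ravel(), minlength=n)
print(f"average-shape tree: {len(shape.spt_edges)} edges, "
      f"{(deg >= 3).sum()} branch point(s) "
      "(the consensus keeps the Y topology)")
print(f"mean point confidence {shape.confidence.mean():.2f} "
      "(lower = that part of the shape is consistent across the cluster)")
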