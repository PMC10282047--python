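"""Build a cell morphology space from synthetic neurons and cluster it.

Generates two morphological classes (sparsely vs heavily branched trees),
samples 50 points per cell, computes geodesic intracellular distances and
the pairwise GW matrix, then clusters and embeds the space.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import morphgw as mg
from morphgw.synthetic import NeuronClassSpec, generate_population

specs = [NeuronClassSpec(n_branches=2, seed=0),
         NeuronClassSpec(n_branches=8, seed=0)]
trees, labels = generate_population(specs, n_per_class=12, seed=11)

cells = []
for i, tree in enumerate(trees):
    cloud = mg.sample_swc_even(tree, 50, cell_id=f"cell{i:02d}")
    cells.append(mg.geodesic_matrix_swc(tree, cloud))

space = mg.gw_pairwise(cells)
print(f"{space.n_cells} cells; median GW distance "
      f"{np.median(space.condensed()):.2f} um "
      "(deformation cost between typical cell shapes)")

clustering = mg.cluster(space, k_graph=10, seed=5)
ari = adjusted_rand_score(labels, clustering.labels)
print(f"Louvain clusters: {clustering.labels.max() + 1}; "
      f"agreement with the planted classes (ARI) = {ari:.2f} "
      "(1.0 = classes perfectly recovered)")

coords = mg.embed_2d(space, n_neighbors=10, seed=5)
spread = coords.std(axis=0)
print(f"2D embedding computed; per-axis spread = {spread[0]:.2f}, {spread[1]:.2f} "
      "(cells with similar branching lie close together)")
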