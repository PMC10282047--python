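"""Find features associated with the morphology space (Laplacian score).

A synthetic feature table with planted localized features, pure-noise
features, and an age-driven confounded feature is tested on a radius
neighbour graph of the space, adjusting for the age covariate.
"""

import morphgw as mg
import numpy as np
from morphgw.synthetic import PlantedFeatureSpec, generate_features

# a morphology space with two communities
rng = np.random.default_rng(3)
N = 60
labels = np.repeat([0, 1], N // 2)
noise = rng.random((N, N))
D = np.where(labels[:, None] != labels[None, :], 8.0, 2.0) + 0.5 * (noise + noise.T)
np.fill_diagonal(D, 0.0)
space = mg.GWSpace(cell_ids=[f"c{i:02d}" for i in range(N)], distances=D)

features, covariates, truth = generate_features(labels, PlantedFeatureSpec(
    n_cells=N, n_features=12, n_localized=3, n_confounded=2,
    strength=3.0, covariate_strength=1.5, seed=7))

graph = mg.radius_graph(space, eps="median")
result = mg.permutation_test(features, graph, covariates=covariates,
                             n_perm=1000, seed=1)
table = result.table.sort_values("q").set_index("feature")
print(table.round(4).to_string())
print()
print(f"planted localized features: {truth['localized']}")
print(f"age-driven (confounded) features: {truth['confounded']}")
print("low score + small q = feature varies along the morphology space; "
      "confounded features are absorbed by the age covariate.")
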