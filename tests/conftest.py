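"""Shared fixtures: small hand-built trees and synthetic cell banks."""

import numpy as np
import pytest

import morphgw as mg
from morphgw.synthetic import NeuronClassSpec, generate_population


@pytest.fixture
def path_tree():
    """Straight 3-node path of total length 10 along x."""
    return mg.NeuronTree(
        node_ids=[1, 2, 3], structure=[1, 3, 3],
        xyz=[[0, 0, 0], [5, 0, 0], [10, 0, 0]], radius=[1, 1, 1],
        parent=[-1, 0, 1],
    )


@pytest.fixture
def l_tree():
    """L-shaped path: unit segment along x then unit segment along y."""
    return mg.NeuronTree(
        node_ids=[1, 2, 3], structure=[1, 3, 3],
        xyz=[[0, 0, 0], [1, 0, 0], [1, 1, 0]], radius=[1, 1, 1],
        parent=[-1, 0, 1],
    )


@pytest.fixture
def y_tree():
    """Y-shaped tree: trunk of length 2, two symmetric arms."""
    return mg.NeuronTree(
        node_ids=np.arange(1, 8), structure=[1] + [3] * 6,
        xyz=[[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 1, 3], [0, 2, 4],
             [0, -1, 3], [0, -2, 4]],
        radius=np.ones(7), parent=[-1, 0, 1, 2, 3, 2, 5],
    )


@pytest.fixture(scope="session")
def random_trees():
    """Ten random branching trees spanning two morphological classes."""
    specs = [NeuronClassSpec(n_branches=2, seed=0),
             NeuronClassSpec(n_branches=6, seed=0)]
    trees, labels = generate_population(specs, 5, seed=21)
    return trees, labels


@pytest.fixture(scope="session")
def geodesic_cells(random_trees):
    """Geodesic intracell matrices (30 points) for the random tree bank."""
    trees, labels = random_trees
    cells = []
    for i, tr in enumerate(trees):
        cloud = mg.sample_swc_even(tr, 30, cell_id=f"cell{i:02d}")
        cells.append(mg.geodesic_matrix_swc(tr, cloud))
    return cells, labels


@pytest.fixture(scope="session")
def blob_space():
    """Synthetic morphology space with two well-separated blobs of 20 cells."""
    rng = np.random.default_rng(7)
    N = 40
    labels = np.repeat([0, 1], 20)
    D = np.where(labels[:, None] != labels[None, :], 8.0, 2.0)
    noise = rng.random((N, N))
    D = D + 0.5 * (noise + noise.T)
    np.fill_diagonal(D, 0.0)
    space = mg.GWSpace(cell_ids=[f"c{i:02d}" for i in range(N)], distances=D)
    return space, labels
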