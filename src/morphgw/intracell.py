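"""Per-cell pairwise distance matrices over sampled points.

Two intracellular metrics are supported.  The Euclidean metric records the
straight-line distance between sampled points and is sensitive to the spatial
arrangement of cell appendages.  The geodesic metric records shortest-path
length along the cell's skeleton or surface and is invariant under bending
deformations, making it sensitive to branching topology rather than pose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import pdist, squareform

from .io import NeuronTree, TriMesh
from .sampling import PointCloud

logger = logging.getLogger(__name__)

__all__ = [
    "IntracellDistanceMatrix",
    "euclidean_matrix",
    "geodesic_matrix_swc",
    "geodesic_matrix_mesh",
]


@dataclass
class IntracellDistanceMatrix:
    """Symmetric pairwise distance matrix among one cell's sampled points."""

    cell_id: str
    metric: str                   # "euclidean" | "geodesic"
    D: np.ndarray                 # (n, n) float, micrometres

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=np.float64)
        n = self.D.shape[0]
        if self.D.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.all(np.isfinite(self.D)):
            raise ValueError("distance matrix has non-finite entries (disconnected cell?)")
        if np.any(self.D < 0) or np.any(np.diag(self.D) != 0):
            raise ValueError("distance matrix must be non-negative with zero diagonal")
        if not np.allclose(self.D, self.D.T, rtol=0, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        self.D = 0.5 * (self.D + self.D.T)

    @property
    def n(self) -> int:
        return self.D.shape[0]


def euclidean_matrix(cloud: PointCloud) -> IntracellDistanceMatrix:
    """Straight-line distances between all pairs of sampled points."""
    D = squareform(pdist(cloud.points))
    dup = np.count_nonzero(squareform(D, checks=False) == 0)
    if dup:
        logger.warning("cell %s: %d duplicate point pairs (zero distance)", cloud.cell_id, dup)
    return IntracellDistanceMatrix(cell_id=cloud.cell_id, metric="euclidean", D=D)


def _all_pairs(graph) -> np.ndarray:
    D = dijkstra(graph, directed=False)
    if not np.all(np.isfinite(D)):
        n_comp, labels = connected_components(graph, directed=False)
        sizes = np.bincount(labels)
        raise ValueError(
            f"sample graph is disconnected ({n_comp} components, sizes {sizes.tolist()})"
        )
    return D


def geodesic_matrix_swc(tree: NeuronTree, cloud: PointCloud) -> IntracellDistanceMatrix:
    """Geodesic (along-the-skeleton) distances between sampled points.

    For walk-sampled clouds the sample graph links each point to its
    predecessor along the root-to-leaf walk (edge weight = arclength between
    them, i.e. the step for even sampling); all-pairs shortest paths on this
    graph give the geodesics.  For clouds without walk structure the exact
    arclength metric of the tree is evaluated at the sampled positions.
    """
    if cloud.pred is not None:
        n = cloud.n
        rows = np.flatnonzero(cloud.pred >= 0)
        graph = coo_matrix(
            (cloud.pred_dist[rows], (rows, cloud.pred[rows])), shape=(n, n)
        ).tocsr()
        D = _all_pairs(graph)
    else:
        D = _tree_arclength_matrix(tree, cloud)
    return IntracellDistanceMatrix(cell_id=cloud.cell_id, metric="geodesic", D=D)


def _tree_arclength_matrix(tree: NeuronTree, cloud: PointCloud) -> np.ndarray:
    """Exact pairwise arclength distances for points located on tree edges."""
    N = tree.n_nodes
    rows = np.arange(1, N)
    w = tree.edge_lengths()
    node_graph = coo_matrix((w, (rows, tree.parent[1:])), shape=(N, N)).tocsr()
    Dnode = dijkstra(node_graph, directed=False)
    if not np.all(np.isfinite(Dnode)):
        raise ValueError("neuron tree is disconnected")
    # each sampled point sits on the edge (parent[v], v) at distance t from v
    v = cloud.provenance
    t = np.linalg.norm(cloud.points - tree.xyz[v], axis=1)
    p = np.where(v > 0, tree.parent[np.maximum(v, 1)], 0)
    n = cloud.n
    D = np.empty((n, n))
    # shortest route passes through one of the two edge endpoints on each side
    via = np.minimum(Dnode[v][:, v] + t[:, None] + t[None, :],
                     Dnode[v][:, p] + t[:, None] + (np.linalg.norm(
                         cloud.points - tree.xyz[p], axis=1))[None, :])
    via = np.minimum(via, Dnode[p][:, v]
                     + np.linalg.norm(cloud.points - tree.xyz[p], axis=1)[:, None]
                     + t[None, :])
    tp = np.linalg.norm(cloud.points - tree.xyz[p], axis=1)
    via = np.minimum(via, Dnode[p][:, p] + tp[:, None] + tp[None, :])
    D = via
    # points on the same edge: direct arclength along the edge
    same = (v[:, None] == v[None, :])
    direct = np.abs(t[:, None] - t[None, :])
    D = np.where(same, direct, D)
    np.fill_diagonal(D, 0.0)
    return D


def geodesic_matrix_mesh(mesh: TriMesh, cloud: PointCloud) -> IntracellDistanceMatrix:
    """Geodesic distances between sampled mesh vertices.

    Distances are shortest paths on the mesh edge graph weighted by edge
    length -- an upper-bound approximation of true surface geodesics that is
    deterministic and dependency-free.  An exact surface-geodesic backend can
    be substituted behind the same contract.
    """
    if mesh.faces.size == 0:
        raise ValueError("mesh has no faces: no edge graph for geodesics")
    V = mesh.n_vertices
    e = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    graph = coo_matrix((w, (e[:, 0], e[:, 1])), shape=(V, V)).tocsr()
    idx = cloud.provenance
    Dsub = dijkstra(graph, directed=False, indices=idx)[:, idx]
    if not np.all(np.isfinite(Dsub)):
        raise ValueError("sampled vertices lie in different mesh components")
    return IntracellDistanceMatrix(cell_id=cloud.cell_id, metric="geodesic", D=Dsub)
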