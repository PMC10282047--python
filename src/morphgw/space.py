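"""Operations on the cell morphology space.

Once the pairwise GW matrix is computed, cells can be clustered (Louvain
community detection on a kNN graph), embedded in 2D (UMAP on the precomputed
distances), and summarized per cluster by a medoid cell and an *average
shape*: the couplings of each cluster member to the medoid re-index the
members' intracellular matrices onto the medoid's points, and the aligned
matrices are averaged.  Rendering the averaged matrix as a k=3 nearest
neighbour graph and taking its shortest-path tree from the soma sample gives
a skeleton-like consensus morphology with a per-point consistency score.
"""

from __future__ import annotations

import logging
import random as _pyrandom
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .gw import GWSpace

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterLabeling",
    "AverageShape",
    "medoid",
    "align_to_medoid",
    "harden_coupling",
    "transport_average",
    "average_morphology_matrix",
    "shape_tree",
    "cluster",
    "embed_2d",
]


@dataclass
class ClusterLabeling:
    """Cluster assignment for every cell plus the parameters that produced it."""

    cell_ids: list[str]
    labels: np.ndarray            # (N,) contiguous integers starting at 0
    k_graph: int
    resolution: float
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            raise ValueError("labels must be contiguous integers from 0")


@dataclass
class AverageShape:
    """Average morphology of a cluster: averaged matrix and its tree rendering."""

    cluster_id: int
    medoid_cell: str
    d_hat: np.ndarray             # (n, n) averaged distance matrix
    knn_edges: np.ndarray         # (E, 2) edges of the k=3 NN graph
    spt_edges: np.ndarray         # (n-1 or fewer, 2) shortest-path-tree edges
    confidence: np.ndarray        # (n,) raw per-point consistency (lower = better)
    confidence_scaled: np.ndarray # (n,) min-max normalized to [0, 1]


# ---------------------------------------------------------------------------
# medoid and alignment
# ---------------------------------------------------------------------------

def medoid(space: GWSpace, subset: list[int] | None = None) -> int:
    """Index of the cell minimizing the sum of distances to the subset.

    Ties are broken toward the smallest cell index.
    """
    idx = np.arange(space.n_cells) if subset is None else np.asarray(subset, dtype=int)
    if len(idx) == 0:
        raise ValueError("empty subset")
    sub = space.distances[np.ix_(idx, idx)]
    sums = sub.sum(axis=1)
    return int(idx[int(np.argmin(sums))])  # argmin returns first minimum


def harden_coupling(T: np.ndarray) -> np.ndarray:
    """Turn a soft coupling into a permutation by max-weight assignment.

    Row ``alpha`` of the result maps medoid point ``alpha`` to cell point
    ``perm[alpha]``.  Hungarian assignment on ``-T`` guarantees a proper
    permutation even for diffuse couplings (row-argmax does not).
    """
    T = np.asarray(T, dtype=np.float64)
    if T.shape[0] != T.shape[1]:
        raise ValueError("hardening requires equal point counts")
    if T.sum() <= 0 or np.any(~np.isfinite(T)):
        raise ValueError("coupling too degenerate to harden")
    rows, cols = linear_sum_assignment(-T)
    perm = np.empty(T.shape[0], dtype=np.int64)
    perm[rows] = cols
    return perm


def align_to_medoid(matrices: list[np.ndarray],
                    couplings: list[np.ndarray],
                    cell_ids: list[str] | None = None) -> list[np.ndarray]:
    """Re-index each cell's distance matrix onto the medoid's points.

    ``couplings[i]`` is the transport plan from the medoid to cell ``i``
    (medoid points along rows).  Each coupling is hardened to a permutation
    and the matrix is conjugated by it, so entry ``(a, b)`` of the result is
    the distance within cell ``i`` between the points matched to medoid
    points ``a`` and ``b``.
    """
    if len(matrices) != len(couplings):
        raise ValueError("need one coupling per matrix")
    out = []
    for i, (D, T) in enumerate(zip(matrices, couplings)):
        D = np.asarray(D, dtype=np.float64)
        try:
            perm = harden_coupling(T)
        except ValueError as e:
            name = cell_ids[i] if cell_ids else str(i)
            raise ValueError(f"cell {name}: {e}") from e
        out.append(D[np.ix_(perm, perm)])
    return out


def transport_average(matrices: list[np.ndarray], couplings: list[np.ndarray],
                      scale: str = "points") -> np.ndarray:
    """Coupling-weighted average of distance matrices onto the medoid indexing.

    Literal one-sided transport: ``d_hat[a, b] = (1/|X|) sum_i sum_g
    T_i[a, g] d_i[g, b]``.  With ``scale="points"`` the result is multiplied
    by ``n`` so that mass-1/n coupling rows average to the micrometre scale;
    ``scale="raw"`` keeps the printed normalization.  Note the second index
    is left in each cell's own ordering; the pipeline uses
    :func:`average_morphology_matrix` on aligned matrices instead, which
    stays symmetric.
    """
    acc = None
    for D, T in zip(matrices, couplings):
        term = np.asarray(T) @ np.asarray(D)
        acc = term if acc is None else acc + term
    acc /= len(matrices)
    if scale == "points":
        acc = acc * acc.shape[0]
    elif scale != "raw":
        raise ValueError("scale must be 'points' or 'raw'")
    return acc


def average_morphology_matrix(aligned: list[np.ndarray],
                              mode: str = "transport") -> np.ndarray:
    """Average a cluster's aligned distance matrices.

    ``mode="transport"``: entrywise mean of the aligned matrices (for
    permutation couplings this equals the coupling-weighted transport onto
    the medoid indexing, kept on the micrometre scale).

    ``mode="thresholded"``: each matrix is divided by its minimum positive
    entry (making adjacent points distance ~1), rounded to integers, clipped
    at 2, then averaged -- an unweighted-graph consensus where entry
    ``(a, b)`` is small when points are adjacent in most cluster members.
    """
    if not aligned:
        raise ValueError("empty cluster")
    mats = [np.asarray(D, dtype=np.float64) for D in aligned]
    n = mats[0].shape[0]
    if any(D.shape != (n, n) for D in mats):
        raise ValueError("all matrices must be n x n")
    if mode == "transport":
        return np.mean(mats, axis=0)
    if mode == "thresholded":
        clipped = []
        for D in mats:
            pos = D[D > 0]
            if pos.size == 0:
                raise ValueError("zero matrix has no positive minimum to rescale by")
            clipped.append(np.clip(np.rint(D / pos.min()), 0, 2))
        return np.mean(clipped, axis=0)
    raise ValueError("mode must be 'transport' or 'thresholded'")


def shape_tree(d_hat: np.ndarray, k: int = 3, root: int = 0,
               mode: str = "thresholded"):
    """Render an averaged matrix as a kNN-graph shortest-path tree.

    Each point is linked to its ``k`` nearest neighbours (ties by index) --
    for a thresholded average this connects each point to the points it is
    most often adjacent to across the cluster -- and the shortest-path tree
    rooted at the soma sample (``root``, the first sampled point) is
    extracted with Dijkstra.  With ``mode="thresholded"`` (input values in
    [0, 2]) edge costs are ``1 - averaged adjacency``, i.e. ``d_hat - 1``
    clipped to [0, 1], so edges that are adjacency edges in every cluster
    member cost ~0 and the tree follows the consensus skeleton; with
    ``mode="metric"`` the averaged distances are used as costs directly.
    The per-point confidence is the summed averaged distance from the point
    to its ``k`` nearest neighbours -- low when the point sits next to the
    same neighbours in most cluster members.  If the kNN graph is
    disconnected, a tree is built per component and a warning issued.
    """
    d_hat = np.asarray(d_hat, dtype=np.float64)
    n = d_hat.shape[0]
    if n < 2:
        raise ValueError("averaged matrix too small")
    if mode == "thresholded":
        cost = np.clip(d_hat - 1.0, 0.0, 1.0)
    elif mode == "metric":
        cost = d_hat
    else:
        raise ValueError("mode must be 'thresholded' or 'metric'")
    k = min(k, n - 1)
    masked = cost + np.diag(np.full(n, np.inf))
    nn = np.argsort(masked, axis=1, kind="stable")[:, :k]
    confidence = np.take_along_axis(d_hat + np.diag(np.full(n, np.inf)),
                                    nn, axis=1).sum(axis=1)

    edges = set()
    for i in range(n):
        for j in nn[i]:
            edges.add((min(i, int(j)), max(i, int(j))))
    knn_edges = np.array(sorted(edges), dtype=np.int64)
    w = cost[knn_edges[:, 0], knn_edges[:, 1]]
    # strictly positive weights so Dijkstra's tree is well-defined; the tiny
    # floor also makes zero-cost runs resolve ties by hop count
    w = np.maximum(w, 1e-12)
    graph = coo_matrix((w, (knn_edges[:, 0], knn_edges[:, 1])), shape=(n, n)).tocsr()

    n_comp, comp = connected_components(graph, directed=False)
    if n_comp > 1:
        logger.warning("kNN graph disconnected (%d components); tree built per component",
                       n_comp)
    roots = [root]
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        if comp[root] != c:
            roots.append(int(members[0]))
    _, predecessors, _ = dijkstra(graph, directed=False, indices=roots,
                                  return_predecessors=True, min_only=True)
    spt = np.array(sorted(
        (min(i, int(p)), max(i, int(p)))
        for i, p in enumerate(predecessors) if p >= 0
    ), dtype=np.int64).reshape(-1, 2)

    span = confidence.max() - confidence.min()
    scaled = (confidence - confidence.min()) / (span if span > 0 else 1.0)
    return knn_edges, spt, confidence, scaled


def build_average_shape(space: GWSpace, subset: list[int],
                        matrices: list[np.ndarray],
                        couplings: list[np.ndarray],
                        cluster_id: int = 0,
                        mode: str = "thresholded") -> AverageShape:
    """Full average-shape pipeline for one cluster.

    ``matrices`` and ``couplings`` are aligned with ``subset``; couplings run
    from the medoid to each member (identity for the medoid itself).
    """
    med = medoid(space, subset)
    aligned = align_to_medoid(matrices, couplings,
                              cell_ids=[space.cell_ids[i] for i in subset])
    d_hat = average_morphology_matrix(aligned, mode=mode)
    knn_edges, spt, conf, conf_scaled = shape_tree(
        d_hat, mode="thresholded" if mode == "thresholded" else "metric")
    return AverageShape(
        cluster_id=cluster_id, medoid_cell=space.cell_ids[med], d_hat=d_hat,
        knn_edges=knn_edges, spt_edges=spt, confidence=conf,
        confidence_scaled=conf_scaled,
    )


# ---------------------------------------------------------------------------
# clustering and embedding
# ---------------------------------------------------------------------------

def _knn_graph_edges(D: np.ndarray, k: int) -> set[tuple[int, int]]:
    N = D.shape[0]
    masked = D + np.diag(np.full(N, np.inf))
    nn = np.argsort(masked, axis=1, kind="stable")[:, :k]
    edges = set()
    for i in range(N):
        for j in nn[i]:
            edges.add((min(i, int(j)), max(i, int(j))))
    return edges


def cluster(space: GWSpace, k_graph: int = 15, resolution: float = 1.0,
            seed: int = 0) -> ClusterLabeling:
    """Louvain community detection on an unweighted kNN graph of the space."""
    N = space.n_cells
    if N < k_graph + 1:
        k_graph = max(1, N - 1)
        logger.warning("k_graph reduced to %d for %d cells", k_graph, N)
    import igraph as ig

    edges = sorted(_knn_graph_edges(space.distances, k_graph))
    g = ig.Graph(n=N, edges=list(edges))
    state = _pyrandom.getstate()
    try:
        _pyrandom.seed(seed)
        part = g.community_multilevel(resolution=resolution)
    finally:
        _pyrandom.setstate(state)
    labels = np.asarray(part.membership, dtype=np.int64)
    # relabel to contiguous ints ordered by first occurrence
    _, labels = np.unique(labels, return_inverse=True)
    return ClusterLabeling(cell_ids=list(space.cell_ids), labels=labels,
                           k_graph=k_graph, resolution=resolution, seed=seed)


def embed_2d(space: GWSpace, n_neighbors: int = 15, seed: int = 0) -> np.ndarray:
    """2D UMAP embedding from the precomputed GW distances (seeded)."""
    N = space.n_cells
    if N < n_neighbors + 1:
        n_neighbors = max(2, N - 1)
    import umap

    reducer = umap.UMAP(n_neighbors=n_neighbors, n_components=2,
                        metric="precomputed", random_state=seed)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(space.distances)
    return np.asarray(coords, dtype=np.float64)
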