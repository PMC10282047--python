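"""Discretize cells into exactly ``n`` points.

Every cell representation (SWC skeleton, surface mesh, 2D mask) is reduced to
a point cloud of a fixed size before distances are computed, so that all
cells live in metric-measure spaces with the same number of support points.

The even SWC sampler reproduces the fixed-step scheme: points are emitted
radially outward from the soma at a constant arclength step, and the step
size giving exactly ``n`` points is located by binary search (the point count
is non-increasing in the step).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import NeuronTree, SegmentationMask, TriMesh

__all__ = [
    "PointCloud",
    "sample_swc_even",
    "sample_swc_random",
    "sample_mesh_vertices",
    "sample_mask_outline",
]

_MAX_BISECT = 64


@dataclass
class PointCloud:
    """``n`` points sampled from one cell.

    ``provenance`` maps each point to the node/vertex index (or contour
    position) it was derived from.  For walk-based SWC sampling, ``pred`` and
    ``pred_dist`` record the preceding sampled point along the root-to-leaf
    walk and the arclength to it; these define the sample graph used for
    geodesic distances.
    """

    cell_id: str
    points: np.ndarray                     # (n, 3) or (n, 2), micrometres
    provenance: np.ndarray                 # (n,) int
    step: float | None = None              # achieved step (even sampling)
    pred: np.ndarray | None = None         # (n,) int, -1 for the root sample
    pred_dist: np.ndarray | None = None    # (n,) float, arclength to pred
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.provenance = np.asarray(self.provenance, dtype=np.int64)
        if self.points.ndim != 2:
            raise ValueError("points must be a 2D array")
        if len(self.points) < 2:
            raise ValueError("a point cloud needs at least 2 points")
        if len(self.provenance) != len(self.points):
            raise ValueError("provenance length mismatch")

    @property
    def n(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# SWC sampling
# ---------------------------------------------------------------------------

def _walk_even(tree: NeuronTree, step: float, collect: bool):
    """Depth-first walk emitting a point every ``step`` micrometres of cable.

    The residual arclength since the last emitted point is carried across
    branch points along each root-to-leaf path, so the emitted positions are
    invariant under subdivision of edges.  Returns the point count, and when
    ``collect`` the positions, provenance and predecessor structure.
    """
    kids = tree.children()
    pts, prov, pred, pdist = [], [], [], []
    count = 1  # the root / soma sample
    if collect:
        pts.append(tree.xyz[0].copy())
        prov.append(0)
        pred.append(-1)
        pdist.append(0.0)
    # stack entries: (node, residual arclength since last sample, last sample index)
    stack = [(0, 0.0, 0)]
    while stack:
        u, residual, last = stack.pop()
        for v in reversed(kids[u]):
            a, b = tree.xyz[u], tree.xyz[v]
            L = float(np.linalg.norm(b - a))
            r, last_v = residual, last
            offset = step - r  # arclength along this edge of the next emission
            while offset <= L + 1e-12 * step:
                count += 1
                if collect:
                    t = min(offset / L, 1.0)
                    pts.append(a + t * (b - a))
                    prov.append(v)
                    pred.append(last_v)
                    pdist.append(step)
                    last_v = len(pts) - 1
                offset += step
            r = L - (offset - step)
            stack.append((v, r, last_v))
    if not collect:
        return count, None
    return count, (np.array(pts), np.array(prov), np.array(pred), np.array(pdist))


def _count_even(tree: NeuronTree, step: float) -> int:
    # must use the identical emission rule as the collecting walk
    return _walk_even(tree, step, collect=False)[0]


def sample_swc_even(tree: NeuronTree, n: int, cell_id: str = "cell") -> PointCloud:
    """Sample exactly ``n`` evenly spaced points from a neuron skeleton.

    Binary search locates the largest arclength step whose walk emits exactly
    ``n`` points (the count is non-increasing in the step); the soma is always
    the first point.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    total = tree.total_length()
    if tree.n_nodes < 2 or total <= 0:
        raise ValueError("tree has no cable to sample (single node or zero length)")

    lo = total / (10.0 * n)
    hi = total
    for _ in range(_MAX_BISECT):
        if _count_even(tree, lo) >= n:
            break
        lo /= 2.0
    if _count_even(tree, lo) < n:
        raise RuntimeError(f"could not bracket a step size yielding {n} points")

    # invariant: count(lo) >= n, count(hi) <= n (largest step wins ties)
    if _count_even(tree, hi) > n:
        raise RuntimeError("even the largest step produces more points than requested")
    for _ in range(_MAX_BISECT):
        mid = 0.5 * (lo + hi)
        if _count_even(tree, mid) >= n:
            lo = mid
        else:
            hi = mid
    step = lo
    count, data = _walk_even(tree, step, collect=True)
    if count != n:
        raise RuntimeError(
            f"binary search did not converge to {n} points (got {count}); "
            "the point count may skip n for this tree"
        )
    pts, prov, pred, pdist = data
    return PointCloud(
        cell_id=cell_id, points=pts, provenance=prov, step=step,
        pred=pred, pred_dist=pdist, source="swc-even",
    )


def sample_swc_random(
    tree: NeuronTree, n: int, seed: int, cell_id: str = "cell"
) -> PointCloud:
    """Sample the soma plus ``n - 1`` points uniform by arclength measure."""
    if n < 2:
        raise ValueError("n must be >= 2")
    lengths = tree.edge_lengths()
    total = float(lengths.sum())
    if tree.n_nodes < 2 or total <= 0:
        raise ValueError("tree has no cable to sample")
    rng = np.random.default_rng(seed)
    edges = rng.choice(len(lengths), size=n - 1, p=lengths / total)
    ts = rng.random(n - 1)
    child = edges + 1  # edge k joins node k+1 to its parent
    a = tree.xyz[tree.parent[child]]
    b = tree.xyz[child]
    pts = np.vstack([tree.xyz[0], a + ts[:, None] * (b - a)])
    prov = np.concatenate([[0], child])
    return PointCloud(
        cell_id=cell_id, points=pts, provenance=prov, source="swc-random"
    )


# ---------------------------------------------------------------------------
# Mesh / mask sampling
# ---------------------------------------------------------------------------

def sample_mesh_vertices(mesh: TriMesh, n: int, cell_id: str = "cell") -> PointCloud:
    """Select ``n`` vertices evenly spaced in file order.

    Mesh vertices are typically stored roughly ordered by spatial proximity,
    so evenly spaced indices approximate even sampling over the surface.
    Index rule: ``round(k * (V - 1) / (n - 1))`` for ``k = 0 .. n-1``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    V = mesh.n_vertices
    if V < n:
        raise ValueError(f"mesh has {V} vertices, fewer than requested n={n}")
    k = np.arange(n, dtype=np.float64)
    idx = np.floor(k * (V - 1) / (n - 1) + 0.5).astype(np.int64)
    return PointCloud(
        cell_id=cell_id, points=mesh.vertices[idx], provenance=idx,
        source="mesh-vertices",
    )


def _moore_trace(pixels: np.ndarray) -> np.ndarray:
    """Trace the closed outer boundary of the single object (Moore tracing).

    Starts at the top-left boundary pixel and proceeds clockwise in image
    coordinates.  Returns the ordered boundary pixel coordinates (row, col).
    """
    rows, cols = np.nonzero(pixels)
    start = (int(rows[0]), int(cols[np.argmin(cols[rows == rows[0]])]))
    # clockwise Moore neighbourhood, starting from "up"
    nbrs = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]

    def fg(p):
        r, c = p
        return 0 <= r < pixels.shape[0] and 0 <= c < pixels.shape[1] and pixels[r, c]

    contour = [start]
    backtrack = (start[0] - 1, start[1])  # above the topmost pixel: background
    current = start
    for _ in range(4 * pixels.size + 8):
        dstart = (backtrack[0] - current[0], backtrack[1] - current[1])
        i0 = nbrs.index(dstart)
        nxt = None
        for j in range(1, 9):
            cand_d = nbrs[(i0 + j) % 8]
            cand = (current[0] + cand_d[0], current[1] + cand_d[1])
            if fg(cand):
                nxt = cand
                backtrack = (current[0] + nbrs[(i0 + j - 1) % 8][0],
                             current[1] + nbrs[(i0 + j - 1) % 8][1])
                break
        if nxt is None or nxt == start:  # isolated pixel / contour closed
            break
        contour.append(nxt)
        current = nxt
    return np.array(contour, dtype=np.float64)


def sample_mask_outline(mask: SegmentationMask, n: int, cell_id: str = "cell") -> PointCloud:
    """Sample ``n`` points at equal arclength spacing along the mask outline.

    The closed boundary contour is traced through pixel centers starting at
    the top-left boundary pixel, clockwise; points are placed every
    ``perimeter / n`` micrometres starting from the contour start.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if mask.pixels.sum() < 2:
        raise ValueError("single-pixel object has no contour")
    contour = _moore_trace(mask.pixels)
    if len(contour) < 2:
        raise ValueError("object contour degenerate (single boundary pixel)")
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perimeter = cum[-1]
    targets = np.arange(n) * perimeter / n
    seg_idx = np.clip(np.searchsorted(cum, targets, side="right") - 1, 0, len(seg) - 1)
    t = (targets - cum[seg_idx]) / np.where(seg[seg_idx] > 0, seg[seg_idx], 1.0)
    pts = closed[seg_idx] + t[:, None] * (closed[seg_idx + 1] - closed[seg_idx])
    # image (row, col) -> (x, y) in micrometres
    xy = np.column_stack([pts[:, 1], pts[:, 0]]) * mask.pixel_size
    return PointCloud(
        cell_id=cell_id, points=xy, provenance=seg_idx.astype(np.int64),
        source="mask-outline",
    )
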