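"""Readers and writers for cell reconstructions and distance matrices.

Supported external representations:

* SWC neuron reconstructions -- a rooted tree of 3D nodes with radii and
  parent pointers, one file per cell.
* Triangular surface meshes (ASCII OBJ / PLY), one file per cell.
* Binary 2D segmentation masks (TIFF / PNG), one object per image.
* A condensed text format for symmetric pairwise distance matrices
  (cell ids in a header, upper-triangular entries one per line).

All coordinates are treated as micrometres; no unit conversion is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "NeuronTree",
    "TriMesh",
    "SegmentationMask",
    "SWCFormatError",
    "read_swc",
    "write_swc",
    "read_mesh",
    "read_mask",
    "read_gw_matrix",
    "write_gw_matrix",
]


class SWCFormatError(ValueError):
    """Raised when an SWC file violates the format or tree invariants."""


@dataclass
class NeuronTree:
    """A neuron reconstruction: a rooted tree of 3D nodes.

    Nodes are stored in topological order (parent before child). ``parent``
    holds, for each node, the *positional index* of its parent in the arrays
    (-1 for the root); original SWC ids are kept in ``node_ids``.
    """

    node_ids: np.ndarray          # (N,) int, original SWC ids
    structure: np.ndarray         # (N,) int, SWC structure codes
    xyz: np.ndarray               # (N, 3) float, micrometres
    radius: np.ndarray            # (N,) float, micrometres
    parent: np.ndarray            # (N,) int, positional parent index, -1 root

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64)
        self.structure = np.asarray(self.structure, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.radius = np.asarray(self.radius, dtype=np.float64)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        n = len(self.node_ids)
        if self.xyz.shape != (n, 3):
            raise ValueError("xyz must have shape (N, 3)")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise SWCFormatError(f"tree must have exactly one root, found {len(roots)}")
        if roots[0] != 0:
            raise SWCFormatError("root must be the first stored node")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise SWCFormatError("parent must precede child in stored order")
        lengths = self.edge_lengths()
        if np.any(lengths <= 0):
            raise SWCFormatError("zero-length edge (child coincides with parent)")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of the edge from each non-root node to its parent."""
        child = self.xyz[1:]
        par = self.xyz[self.parent[1:]]
        return np.linalg.norm(child - par, axis=1)

    def total_length(self) -> float:
        """Total cable length (sum of all edge lengths), micrometres."""
        return float(self.edge_lengths().sum())

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            out[self.parent[i]].append(i)
        return out


@dataclass
class TriMesh:
    """A triangular surface mesh; vertex order is preserved from the file."""

    vertices: np.ndarray          # (V, 3) float, micrometres
    faces: np.ndarray             # (F, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        V = len(self.vertices)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= V:
                raise ValueError("face index out of range")
            a, b, c = self.faces.T
            if np.any((a == b) | (b == c) | (a == c)):
                raise ValueError("degenerate face with repeated vertex index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class SegmentationMask:
    """A binary 2D segmentation mask holding exactly one 8-connected object."""

    pixels: np.ndarray            # (H, W) bool
    pixel_size: float = 1.0       # micrometres / pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(path: str | Path, resort: bool = False) -> NeuronTree:
    """Read a whitespace-separated SWC file into a :class:`NeuronTree`.

    Comment lines starting with ``#`` and blank lines are skipped; columns
    beyond the standard seven are ignored.  By default a file in which any
    child row precedes its parent row is rejected as "unsorted"; pass
    ``resort=True`` to topologically re-sort instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise SWCFormatError(f"{path}:{lineno}: expected >=7 columns, got {len(parts)}")
        rows.append(
            (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
             float(parts[4]), float(parts[5]), int(parts[6]))
        )
    if not rows:
        raise SWCFormatError(f"{path}: no data rows")

    ids = np.array([r[0] for r in rows], dtype=np.int64)
    if len(np.unique(ids)) != len(ids):
        raise SWCFormatError(f"{path}: duplicate node ids")
    parents_raw = np.array([r[6] for r in rows], dtype=np.int64)
    id_to_pos = {int(i): k for k, i in enumerate(ids)}

    roots = np.flatnonzero(parents_raw == -1)
    if len(roots) == 0:
        raise SWCFormatError(f"{path}: no root node (parent -1)")
    if len(roots) > 1:
        raise SWCFormatError(f"{path}: multiple roots (nodes {ids[roots].tolist()})")
    for pid in parents_raw:
        if pid != -1 and int(pid) not in id_to_pos:
            raise SWCFormatError(f"{path}: dangling parent id {int(pid)}")

    order = np.arange(len(rows))
    sorted_ok = all(
        parents_raw[k] == -1 or id_to_pos[int(parents_raw[k])] < k
        for k in range(len(rows))
    )
    if not sorted_ok:
        if not resort:
            raise SWCFormatError(
                f"{path}: unsorted SWC (a child precedes its parent); "
                "pass resort=True to re-sort"
            )
        order = _toposort(parents_raw, id_to_pos, roots[0])

    ids = ids[order]
    id_to_pos = {int(i): k for k, i in enumerate(ids)}
    parent_pos = np.array(
        [-1 if rows[o][6] == -1 else id_to_pos[rows[o][6]] for o in order],
        dtype=np.int64,
    )
    return NeuronTree(
        node_ids=ids,
        structure=np.array([rows[o][1] for o in order]),
        xyz=np.array([[rows[o][2], rows[o][3], rows[o][4]] for o in order]),
        radius=np.array([rows[o][5] for o in order]),
        parent=parent_pos,
    )


def _toposort(parents_raw: np.ndarray, id_to_pos: dict[int, int], root: int) -> np.ndarray:
    n = len(parents_raw)
    kids: list[list[int]] = [[] for _ in range(n)]
    for k in range(n):
        if parents_raw[k] != -1:
            kids[id_to_pos[int(parents_raw[k])]].append(k)
    order, stack = [], [int(root)]
    while stack:
        k = stack.pop()
        order.append(k)
        stack.extend(reversed(kids[k]))
    if len(order) != n:
        raise SWCFormatError("disconnected SWC: some nodes unreachable from the root")
    return np.array(order, dtype=np.int64)


def write_swc(tree: NeuronTree, path: str | Path) -> None:
    """Write a :class:`NeuronTree` as a sorted 7-column SWC file."""
    lines = ["# written by morphgw"]
    for k in range(tree.n_nodes):
        pid = -1 if tree.parent[k] < 0 else int(tree.node_ids[tree.parent[k]])
        x, y, z = tree.xyz[k]
        lines.append(
            f"{int(tree.node_ids[k])} {int(tree.structure[k])} "
            f"{x:.17g} {y:.17g} {z:.17g} {tree.radius[k]:.17g} {pid}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path) -> TriMesh:
    """Read an ASCII OBJ or PLY mesh, preserving vertex order.

    A mesh with zero faces is accepted as an ordered point cloud (vertex-order
    sampling needs only the vertices) and flagged in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import trimesh as _trimesh

    loaded = _trimesh.load(str(path), process=False)
    if isinstance(loaded, _trimesh.Scene):
        raise ValueError(f"{path}: multi-geometry scene files are not supported")
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(getattr(loaded, "faces", np.empty((0, 3))),
                       dtype=np.int64).reshape(-1, 3)
    if faces.size == 0:
        logger.info("mesh %s has no faces; treating as ordered point cloud", path)
    return TriMesh(vertices=vertices, faces=faces)


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def read_mask(path: str | Path, pixel_size: float = 1.0) -> SegmentationMask:
    """Read a single-channel image as a binary mask (nonzero = foreground).

    The mask must contain exactly one 8-connected foreground component.
    """
    import imageio.v3 as iio

    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        if img.shape[2] not in (1,):
            raise ValueError("multi-channel image is not a segmentation mask")
        img = img[..., 0]
    return mask_from_array(img, pixel_size)


def mask_from_array(img: np.ndarray, pixel_size: float = 1.0) -> SegmentationMask:
    """Binarize a 2D array and validate the single-object invariant."""
    pixels = np.asarray(img) != 0
    if not pixels.any():
        raise ValueError("empty mask: no foreground pixels")
    _, n_comp = ndimage.label(pixels, structure=np.ones((3, 3), dtype=int))
    if n_comp > 1:
        raise ValueError(f"multiple objects in mask ({n_comp} components)")
    return SegmentationMask(pixels=pixels, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# Condensed distance-matrix text format
# ---------------------------------------------------------------------------
# Layout:  line 1: "morphgw-distance-matrix v1"
#          line 2: tab-separated cell ids (N of them)
#          next N*(N-1)/2 lines: upper-triangular entries, row-major,
#          printed with 17 significant digits (round-trip exact for float64).

_MAGIC = "morphgw-distance-matrix v1"


def write_gw_matrix(cell_ids: list[str], matrix: np.ndarray, path: str | Path) -> None:
    """Write a symmetric zero-diagonal distance matrix in condensed text form."""
    matrix = np.asarray(matrix, dtype=np.float64)
    n = len(cell_ids)
    if matrix.shape != (n, n):
        raise ValueError("matrix shape does not match number of cell ids")
    if not np.array_equal(matrix, matrix.T):
        raise ValueError("refusing to write an asymmetric matrix")
    if np.any(np.diag(matrix) != 0):
        raise ValueError("refusing to write a matrix with nonzero diagonal")
    if np.any(matrix < 0) or not np.all(np.isfinite(matrix)):
        raise ValueError("distances must be finite and non-negative")
    cond = squareform(matrix, checks=False)
    lines = [_MAGIC, "\t".join(str(c) for c in cell_ids)]
    lines.extend(f"{v:.17g}" for v in cond)
    Path(path).write_text("\n".join(lines) + "\n")


def read_gw_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a condensed distance-matrix file; returns (cell_ids, square matrix)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _MAGIC:
        raise ValueError(f"{path}: not a morphgw distance-matrix file")
    cell_ids = lines[1].split("\t")
    n = len(cell_ids)
    expected = n * (n - 1) // 2
    values = [float(v) for v in lines[2:] if v.strip()]
    if len(values) != expected:
        raise ValueError(
            f"{path}: expected {expected} condensed entries for {n} cells, got {len(values)}"
        )
    cond = np.array(values, dtype=np.float64)
    if np.any(cond < 0):
        raise ValueError(f"{path}: negative distance entry")
    if not np.all(np.isfinite(cond)):
        raise ValueError(f"{path}: non-finite distance entry")
    return cell_ids, squareform(cond)
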