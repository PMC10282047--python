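"""Synthetic neurons, meshes, masks and feature tables with planted structure.

These generators define the study conditions for the test suite and the
examples: random branching trees whose branch count separates morphological
classes, rigid / bending deformations that probe the invariances of the two
intracellular metrics, and feature tables with planted localized features
and an age-like covariate for calibrating the association test.  All
generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import NeuronTree
from .sampling import PointCloud

__all__ = [
    "NeuronClassSpec",
    "PlantedFeatureSpec",
    "generate_neuron",
    "generate_population",
    "rigid_transform",
    "bend_tree",
    "generate_features",
    "icosphere",
    "disk_mask",
]


@dataclass
class NeuronClassSpec:
    """Growth parameters of one synthetic morphological class.

    A trunk is grown from the soma, then ``n_branches`` side-branches sprout
    from uniformly chosen existing nodes, each deflected from its parent
    direction by a Gaussian angle.  Nodes are laid down every
    ``segment_step`` micrometres; branch lengths are Gaussian.
    """

    n_branches: int = 4
    branch_length_mean: float = 50.0      # micrometres
    branch_length_sd: float = 10.0        # micrometres
    branch_angle_sd: float = 0.6          # radians
    segment_step: float = 5.0             # micrometres
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.branch_length_mean <= 0 or self.branch_length_sd < 0
                or self.segment_step <= 0 or self.branch_angle_sd < 0
                or self.n_branches < 0):
            raise ValueError("all growth parameters must be positive")


@dataclass
class PlantedFeatureSpec:
    """Planted structure of a synthetic feature table."""

    n_cells: int = 60
    n_features: int = 20
    n_localized: int = 5
    strength: float = 3.0                 # community mean shift, SD units
    n_confounded: int = 0                 # features driven by the covariate only
    covariate_strength: float = 1.0       # per-age-unit shift of confounded features
    seed: int = 0


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-random proper rotation matrix via QR of a Gaussian matrix."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def _deflect(direction: np.ndarray, angle_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate ``direction`` by a Gaussian angle about a random orthogonal axis."""
    if angle_sd == 0:
        return direction.copy()
    angle = rng.normal(0.0, angle_sd)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    axis1 = _unit(np.cross(direction, helper))
    axis2 = np.cross(direction, axis1)
    phi = rng.uniform(0, 2 * np.pi)
    axis = np.cos(phi) * axis1 + np.sin(phi) * axis2
    return _unit(np.cos(angle) * direction + np.sin(angle) * np.cross(axis, direction))


def generate_neuron(spec: NeuronClassSpec, cell_id: str = "cell") -> NeuronTree:
    """Grow a random tree from a soma node; seeded and deterministic.

    With ``n_branches=0`` and zero spread parameters the result is a
    straight path of exactly ``branch_length_mean`` total length.
    """
    rng = np.random.default_rng(spec.seed)
    xyz = [np.zeros(3)]
    parent = [-1]
    directions = {0: np.array([0.0, 0.0, 1.0])}

    def grow(from_node: int, direction: np.ndarray) -> None:
        length = spec.branch_length_mean
        if spec.branch_length_sd > 0:
            length = max(spec.segment_step,
                         rng.normal(spec.branch_length_mean, spec.branch_length_sd))
        remaining = length
        node = from_node
        d = direction
        while remaining > 1e-9:
            step = min(spec.segment_step, remaining)
            d = _deflect(d, spec.branch_angle_sd * 0.2, rng)  # gentle meander
            new_xyz = xyz[node] + step * d
            xyz.append(new_xyz)
            parent.append(node)
            node = len(xyz) - 1
            directions[node] = d
            remaining -= step

    grow(0, directions[0])
    for _ in range(spec.n_branches):
        origin = int(rng.integers(1, len(xyz)))
        d = _deflect(directions[origin], max(spec.branch_angle_sd, 1e-12), rng)
        grow(origin, d)

    n = len(xyz)
    return NeuronTree(
        node_ids=np.arange(1, n + 1),
        structure=np.concatenate([[1], np.full(n - 1, 3)]),
        xyz=np.array(xyz),
        radius=np.full(n, 0.5),
        parent=np.array(parent),
    )


def generate_population(specs: list[NeuronClassSpec], n_per_class: int,
                        seed: int = 0) -> tuple[list[NeuronTree], np.ndarray]:
    """Generate ``n_per_class`` neurons for each class spec; returns trees, labels."""
    rng = np.random.default_rng(seed)
    trees, labels = [], []
    for c, spec in enumerate(specs):
        for _ in range(n_per_class):
            s = NeuronClassSpec(**{**spec.__dict__, "seed": int(rng.integers(2**31 - 1))})
            trees.append(generate_neuron(s))
            labels.append(c)
    return trees, np.array(labels)


def rigid_transform(obj: NeuronTree | PointCloud, seed: int = 0,
                    reflect: bool = False):
    """Random rotation + translation of a tree or cloud (optionally reflected).

    Euclidean intracellular distance matrices are unchanged by construction.
    """
    rng = np.random.default_rng(seed)
    R = _random_rotation(rng)
    if reflect:
        R = R @ np.diag([1.0, 1.0, -1.0])
    t = rng.normal(scale=100.0, size=3)
    if isinstance(obj, NeuronTree):
        return NeuronTree(
            node_ids=obj.node_ids.copy(), structure=obj.structure.copy(),
            xyz=obj.xyz @ R.T + t, radius=obj.radius.copy(),
            parent=obj.parent.copy(),
        )
    return PointCloud(
        cell_id=obj.cell_id, points=obj.points @ R.T + t,
        provenance=obj.provenance.copy(), step=obj.step,
        pred=None if obj.pred is None else obj.pred.copy(),
        pred_dist=None if obj.pred_dist is None else obj.pred_dist.copy(),
        source=obj.source,
    )


def bend_tree(tree: NeuronTree, joint: int, angle: float,
              axis: np.ndarray | None = None, seed: int = 0) -> NeuronTree:
    """Rotate the subtree below ``joint`` about an axis through the joint.

    Arclengths along every edge are preserved, so geodesic intracellular
    distances are exactly unchanged while Euclidean distances across the
    joint change (unless ``angle`` is 0).
    """
    if not 0 <= joint < tree.n_nodes:
        raise ValueError("joint node out of range")
    if axis is None:
        axis = _unit(np.random.default_rng(seed).normal(size=3))
    else:
        axis = _unit(np.asarray(axis, dtype=np.float64))
    # Rodrigues rotation about the joint position
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    in_subtree = np.zeros(tree.n_nodes, dtype=bool)
    for i in range(joint + 1, tree.n_nodes):
        if tree.parent[i] == joint or in_subtree[tree.parent[i]]:
            in_subtree[i] = True
    xyz = tree.xyz.copy()
    pivot = tree.xyz[joint]
    xyz[in_subtree] = (xyz[in_subtree] - pivot) @ R.T + pivot
    return NeuronTree(
        node_ids=tree.node_ids.copy(), structure=tree.structure.copy(),
        xyz=xyz, radius=tree.radius.copy(), parent=tree.parent.copy(),
    )


def generate_features(communities: np.ndarray, spec: PlantedFeatureSpec):
    """Synthesize a feature table with planted localized features.

    Localized features are a community indicator plus unit Gaussian noise
    scaled so the planted shift is ``strength`` in SD units; null features
    are iid Gaussian; confounded features depend on the age covariate only.
    Returns ``(features, covariates, truth)`` where ``truth`` lists the
    planted localized and confounded feature names.
    """
    communities = np.asarray(communities)
    n = len(communities)
    if n != spec.n_cells:
        raise ValueError("communities length must equal spec.n_cells")
    rng = np.random.default_rng(spec.seed)
    target = communities == communities[0]
    # age is itself localized (one community skews older), so that
    # age-driven features are significant only without adjustment
    age = np.clip(np.rint(2.0 + 1.5 * target + rng.normal(0, 1.0, n)), 1, 5)
    cols, names = [], []
    localized, confounded = [], []
    for g in range(spec.n_features):
        name = f"feat_{g:03d}"
        noise = rng.normal(size=n)
        if g < spec.n_localized:
            cols.append(spec.strength * target.astype(float) + noise)
            localized.append(name)
        elif g < spec.n_localized + spec.n_confounded:
            cols.append(spec.covariate_strength * age + noise)
            confounded.append(name)
        else:
            cols.append(noise)
        names.append(name)
    features = pd.DataFrame(np.column_stack(cols), columns=names)
    covariates = pd.DataFrame({"age": age})
    truth = {"localized": localized, "confounded": confounded}
    return features, covariates, truth


# ---------------------------------------------------------------------------
# simple geometric fixtures
# ---------------------------------------------------------------------------

def icosphere(subdivisions: int = 3, radius: float = 1.0):
    """Vertices and faces of a subdivided icosahedron (unit-ish sphere mesh)."""
    import trimesh as _trimesh

    m = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return np.asarray(m.vertices, dtype=np.float64), np.asarray(m.faces, dtype=np.int64)


def disk_mask(radius: int = 20, pad: int = 4) -> np.ndarray:
    """Binary raster of a filled disk, for mask-sampling tests."""
    size = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[:size, :size]
    return ((yy - c) ** 2 + (xx - c) ** 2 <= radius**2).astype(np.uint8)
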