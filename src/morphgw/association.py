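"""Feature association on the morphology space via the Laplacian score.

A feature (gene expression, an electrophysiological property, a mutation
indicator) is *localized* in the morphology space when morphologically
neighbouring cells tend to share its value.  The Laplacian score of feature
``f`` on the radius neighbour graph with adjacency ``A`` is

.. math::

    C = \\frac{\\sum_{ij} (f_i - f_j)^2 A_{ij}}{\\mathrm{Var}(f)}

(sum over ordered pairs, population variance).  Low scores indicate
localization.  Significance is assessed by a one-tailed permutation test; a
set of covariates can be adjusted for by simultaneously permuting feature
and covariates, regressing the feature's null scores on the covariates' null
scores, and using the regression residuals as the null distribution for the
covariate-adjusted observed score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import laplacian as _graph_laplacian

from .gw import GWSpace

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborGraph",
    "AssociationResult",
    "radius_graph",
    "laplacian_score",
    "permutation_test",
    "prepare_expression",
    "benjamini_hochberg",
]


@dataclass
class NeighborGraph:
    """Binary radius-neighbour graph over the morphology space."""

    A: np.ndarray                 # (N, N) symmetric 0/1, zero diagonal
    eps: float                    # radius, micrometres

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if not np.array_equal(self.A, self.A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("adjacency must have zero diagonal")


def radius_graph(space: GWSpace, eps: float | str = "median") -> NeighborGraph:
    """Adjacency ``A_ij = 1`` iff ``0 < GW(i, j) <= eps``.

    ``eps="median"`` (the default scale) uses the median off-diagonal GW
    distance.  Isolated nodes are allowed and counted in the log.
    """
    D = space.distances
    if isinstance(eps, str):
        if eps != "median":
            raise ValueError("eps must be a positive number or 'median'")
        eps_val = float(np.median(space.condensed()))
    else:
        eps_val = float(eps)
        if eps_val <= 0:
            raise ValueError("eps must be > 0")
    A = (D <= eps_val).astype(np.int8)
    np.fill_diagonal(A, 0)
    isolated = int(np.sum(A.sum(axis=1) == 0))
    if isolated:
        logger.info("radius graph: %d isolated cells at eps=%.4g", isolated, eps_val)
    return NeighborGraph(A=A, eps=eps_val)


def laplacian_score(f: np.ndarray, A: np.ndarray | NeighborGraph) -> float:
    """Laplacian score of a feature vector on the neighbour graph.

    Computed as ``2 f'Lf / Var(f)`` with ``L`` the unnormalized graph
    Laplacian, which equals the ordered-pair sum of squared neighbour
    differences divided by the population variance.
    """
    A = A.A if isinstance(A, NeighborGraph) else np.asarray(A)
    f = np.asarray(f, dtype=np.float64)
    var = f.var()  # population variance (divisor N)
    if var == 0:
        raise ValueError("zero-variance feature: Laplacian score undefined")
    L = _graph_laplacian(A.astype(np.float64))
    return float(2.0 * f @ L @ f / var)


def _scores_batch(F: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Laplacian scores of many feature vectors at once (rows of ``F``)."""
    deg = A.sum(axis=1).astype(np.float64)
    var = F.var(axis=1)
    quad = np.einsum("ki,i,ki->k", F, deg, F) - np.einsum("ki,ij,kj->k", F, A, F)
    return 2.0 * quad / var


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted q-values."""
    p = np.asarray(p, dtype=np.float64)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


@dataclass
class AssociationResult:
    """Per-feature association statistics."""

    table: pd.DataFrame           # columns: feature, score, adjusted_score, p, q
    beta: dict[str, np.ndarray]   # per-feature null-regression coefficients
    n_permutations: int
    seed: int


def permutation_test(
    features: pd.DataFrame,
    A: np.ndarray | NeighborGraph,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> AssociationResult:
    """One-tailed permutation test of Laplacian-score localization.

    For each permutation replicate a single shared permutation is applied to
    the feature and to every covariate, and all scores are recomputed.  With
    covariates, the feature's null scores are regressed (ordinary least
    squares with intercept) on the covariates' null scores; the residuals
    form the null distribution, against which the covariate-adjusted
    observed score ``C - b0 - sum_m b_m C_cov_m`` is compared one-tailed
    (low scores significant).  Without covariates the raw null scores are
    used directly.  p-values use the add-one rule; q-values are BH across
    all tested features.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    A = A.A if isinstance(A, NeighborGraph) else np.asarray(A)
    A = A.astype(np.float64)
    N = A.shape[0]
    if len(features) != N:
        raise ValueError("feature rows must align with the graph")
    names = list(features.columns)
    F = features.to_numpy(dtype=np.float64).T        # (G, N)
    if np.isnan(F).any():
        raise ValueError("features contain NaN after preprocessing")
    const = F.var(axis=1) == 0
    if const.any():
        bad = [names[i] for i in np.flatnonzero(const)]
        raise ValueError(f"zero-variance features cannot be tested: {bad}")

    H = None
    if covariates is not None and covariates.shape[1] > 0:
        H = covariates.to_numpy(dtype=np.float64).T  # (M, N)
        if len(covariates) != N:
            raise ValueError("covariate rows must align with the graph")
        if np.any(H.var(axis=1) == 0):
            raise ValueError("zero-variance covariate")

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(N) for _ in range(n_perm)])  # (P, N)

    obs = _scores_batch(F, A)                                      # (G,)
    null_F = np.stack([_scores_batch(F[:, pi], A) for pi in perms], axis=1)  # (G, P)

    betas: dict[str, np.ndarray] = {}
    if H is None:
        adj = obs.copy()
        null_resid = null_F
        for g, name in enumerate(names):
            betas[name] = np.zeros(1)
    else:
        obs_H = _scores_batch(H, A)                                # (M,)
        null_H = np.stack([_scores_batch(H[:, pi], A) for pi in perms], axis=1)  # (M, P)
        X = np.column_stack([np.ones(n_perm), null_H.T])           # (P, 1+M)
        coef, *_ = np.linalg.lstsq(X, null_F.T, rcond=None)        # (1+M, G)
        null_resid = null_F - (X @ coef).T
        adj = obs - coef[0] - obs_H @ coef[1:]
        for g, name in enumerate(names):
            betas[name] = coef[:, g].copy()

    # one-tailed: small scores / residuals indicate localization; the tiny
    # tolerance counts exact ties (e.g. a feature equal to its covariate,
    # where all residuals are zero up to round-off) as non-extreme
    atol = 1e-9 * np.maximum(1.0, np.abs(obs))
    p = (1.0 + np.sum(null_resid <= (adj + atol)[:, None], axis=1)) / (n_perm + 1.0)
    q = benjamini_hochberg(p)
    table = pd.DataFrame({
        "feature": names,
        "score": obs,
        "adjusted_score": adj,
        "p": p,
        "q": q,
    })
    return AssociationResult(table=table, beta=betas, n_permutations=n_perm, seed=seed)


def prepare_expression(
    counts: pd.DataFrame,
    scale: float = 5000.0,
    min_detect: float = 0.05,
    max_detect: float = 0.90,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize a cells-by-genes count table for Laplacian-score testing.

    Counts are size-normalized per cell (divided by the cell's total),
    multiplied by ``scale`` and log1p-transformed:
    ``log(1 + scale * size-normalized expression)``.  Genes detected in
    fewer than ``min_detect`` or at least ``max_detect`` of cells are
    dropped.  Returns the normalized kept-gene table and a kept/dropped
    report with detection rates.
    """
    X = counts.to_numpy(dtype=np.float64)
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        zero = list(counts.index[totals == 0])
        raise ValueError(f"cells with zero total count: {zero}")
    norm = np.log1p(scale * X / totals[:, None])
    detect = (X > 0).mean(axis=0)
    keep = (detect >= min_detect) & (detect < max_detect)
    report = pd.DataFrame({
        "gene": counts.columns,
        "detection_rate": detect,
        "kept": keep,
    })
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("prepare_expression: dropped %d/%d genes outside [%g, %g) detection",
                    n_drop, len(keep), min_detect, max_detect)
    out = pd.DataFrame(norm[:, keep], index=counts.index,
                       columns=counts.columns[keep])
    return out, report
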