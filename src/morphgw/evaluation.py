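"""Benchmarking statistics for morphology spaces.

Three ways to quantify how well a distance matrix separates labelled cell
groups: a median-based cell-type separation (CTS) score, cross-validated
k-nearest-neighbour classification (accuracy and multiclass Matthews
correlation coefficient), and per-pair 2-simplex coordinates comparing
distances across data modalities (morphology / transcriptome /
electrophysiology).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "cts_score",
    "knn_cv_classify",
    "mcc",
    "modality_simplex",
    "ModalityDistances",
]


def cts_score(distances: np.ndarray, labels) -> float:
    """Median-based group-discrimination (cell-type separation) score.

    For each label: the ratio of the median between-group distance (members
    vs non-members) to the median within-group distance (pairs inside the
    label).  The score is the mean of the per-label ratios; 1 means no
    separation, larger is better.  Invariant under global rescaling of the
    distance matrix.  Every label needs at least two members.
    """
    D = np.asarray(distances, dtype=np.float64)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two labels")
    iu = np.triu_indices(D.shape[0], k=1)
    ratios = []
    for lab in uniq:
        members = labels == lab
        if members.sum() < 2:
            raise ValueError(f"label {lab!r} has fewer than 2 members")
        pair_within = members[iu[0]] & members[iu[1]]
        pair_between = members[iu[0]] ^ members[iu[1]]
        within = np.median(D[iu][pair_within])
        between = np.median(D[iu][pair_between])
        if within == 0:
            raise ValueError(f"label {lab!r}: zero median within-group distance")
        ratios.append(between / within)
    return float(np.mean(ratios))


def _knn_predict(D_test_train: np.ndarray, train_labels: np.ndarray, k: int,
                 classes: np.ndarray) -> np.ndarray:
    """Majority vote among the k nearest training cells.

    Ties are broken by the smallest summed distance among tied classes,
    then by label order.
    """
    order = np.argsort(D_test_train, axis=1, kind="stable")[:, :k]
    pred = np.empty(D_test_train.shape[0], dtype=classes.dtype)
    for t in range(D_test_train.shape[0]):
        nbr = order[t]
        lab = train_labels[nbr]
        dist = D_test_train[t, nbr]
        best, best_key = None, None
        for c in classes:
            m = lab == c
            votes = int(m.sum())
            if votes == 0:
                continue
            key = (-votes, float(dist[m].sum()))
            if best_key is None or key < best_key:
                best, best_key = c, key
        pred[t] = best
    return pred


def knn_cv_classify(distances: np.ndarray, labels, k: int = 10, folds: int = 7,
                    n_repeats: int = 10, seed: int = 0):
    """Cross-validated kNN classification on a precomputed distance matrix.

    Stratified ``folds``-fold cross-validation, repeated ``n_repeats`` times
    with different fold-assignment seeds; each repeat reports the pooled
    accuracy and the multiclass MCC of the pooled confusion matrix.  Returns
    ``(mean_accuracy, mean_mcc, per_repeat)`` where ``per_repeat`` is an
    ``(n_repeats, 2)`` array of (accuracy, mcc).
    """
    D = np.asarray(distances, dtype=np.float64)
    labels = np.asarray(labels)
    N = D.shape[0]
    if N < folds:
        raise ValueError("fewer cells than folds")
    classes, y = np.unique(labels, return_inverse=True)
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError(
            f"stratification failure: smallest class has {counts.min()} members "
            f"for {folds} folds"
        )
    per_repeat = np.empty((n_repeats, 2))
    rng = np.random.default_rng(seed)
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for train, test in skf.split(np.zeros(N), y):
            pred = _knn_predict(D[np.ix_(test, train)], y[train],
                                min(k, len(train)), np.arange(len(classes)))
            for yt, yp in zip(y[test], pred):
                confusion[yt, yp] += 1
        acc = np.trace(confusion) / confusion.sum()
        per_repeat[r] = (acc, mcc(confusion))
    return float(per_repeat[:, 0].mean()), float(per_repeat[:, 1].mean()), per_repeat


def mcc(confusion: np.ndarray) -> float:
    """Multiclass Matthews correlation coefficient of a confusion matrix.

    Generalized (Gorodkin) form; reduces to the familiar binary closed form
    for 2x2 tables.  Degenerate tables (a single observed or predicted
    class) score 0.
    """
    C = np.asarray(confusion, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(C < 0):
        raise ValueError("confusion matrix must be non-negative")
    s = C.sum()
    if s == 0:
        raise ValueError("all-zero confusion matrix")
    c = np.trace(C)
    t = C.sum(axis=1)   # true-class totals
    p = C.sum(axis=0)   # predicted-class totals
    num = c * s - t @ p
    den = np.sqrt((s**2 - p @ p) * (s**2 - t @ t))
    if den == 0:
        return 0.0
    return float(np.clip(num / den, -1.0, 1.0))


@dataclass
class ModalityDistances:
    """Per-pair standardized log-distances and their 2-simplex coordinates."""

    pair_index: np.ndarray        # (P, 2) cell index pairs (upper triangle)
    z: dict                       # modality -> (P,) standardized log-distance
    coords: np.ndarray            # (P, 3): (dM-dT, dT-dE, dE-dM), rows sum to 0
    n_skipped: int                # pairs dropped because of a zero distance


def modality_simplex(dM: np.ndarray, dT: np.ndarray, dE: np.ndarray,
                     trim: float | None = None) -> ModalityDistances:
    """2-simplex coordinates of per-pair cross-modality distance discrepancies.

    Each modality's off-diagonal pairwise distances are logged and
    z-standardized independently; each cell pair then gets the coordinates
    ``(dM - dT, dT - dE, dE - dM)``, which sum to zero exactly.  Pairs with
    a zero distance in any modality (log undefined) are skipped and counted.
    ``trim`` (e.g. 0.98) restricts to the middle fraction of each axis, a
    plotting-export convenience.
    """
    mats = {"M": np.asarray(dM, float), "T": np.asarray(dT, float),
            "E": np.asarray(dE, float)}
    n = mats["M"].shape[0]
    for name, D in mats.items():
        if D.shape != (n, n):
            raise ValueError("all three matrices must cover the same cells")
    iu = np.triu_indices(n, k=1)
    vals = {name: D[iu] for name, D in mats.items()}
    ok = np.ones(len(iu[0]), dtype=bool)
    for v in vals.values():
        ok &= v > 0
    n_skipped = int((~ok).sum())
    z = {}
    for name, v in vals.items():
        lv = np.log(v[ok])
        sd = lv.std()
        z[name] = (lv - lv.mean()) / (sd if sd > 0 else 1.0)
    c0 = z["M"] - z["T"]
    c1 = z["T"] - z["E"]
    coords = np.column_stack([c0, c1, -(c0 + c1)])  # closes the sum exactly
    pair_index = np.column_stack([iu[0][ok], iu[1][ok]])
    if trim is not None:
        lo, hi = (1 - trim) / 2, 1 - (1 - trim) / 2
        keep = np.ones(len(coords), dtype=bool)
        for a in range(3):
            qlo, qhi = np.quantile(coords[:, a], [lo, hi])
            keep &= (coords[:, a] >= qlo) & (coords[:, a] <= qhi)
        coords, pair_index = coords[keep], pair_index[keep]
        z = {name: v[keep] for name, v in z.items()}
    return ModalityDistances(pair_index=pair_index, z=z, coords=coords,
                             n_skipped=n_skipped)
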