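"""Morphology-space algebra: medoid, alignment, average shapes, clustering."""

import itertools

import numpy as np
import pytest

import morphgw as mg


class TestMedoid:
    def test_row_sum_argmin(self):
        D = np.array([[0, 1, 4], [1, 0, 2], [4, 2, 0]], dtype=float)
        space = mg.GWSpace(cell_ids=["a", "b", "c"], distances=D)
        assert mg.medoid(space) == 1  # row sums 5, 3, 6

    def test_singleton_subset(self, blob_space):
        space, _ = blob_space
        assert mg.medoid(space, [7]) == 7

    def test_tie_goes_to_smallest_index(self):
        D = np.ones((4, 4)) - np.eye(4)
        space = mg.GWSpace(cell_ids=list("abcd"), distances=D)
        assert mg.medoid(space) == 0

    def test_empty_subset(self, blob_space):
        space, _ = blob_space
        with pytest.raises(ValueError, match="empty"):
            mg.medoid(space, [])

    def test_minimizes_over_all_subsets(self, blob_space):
        """Brute-force check of the medoid property on small subsets."""
        space, _ = blob_space
        rng = np.random.default_rng(0)
        for _ in range(10):
            subset = sorted(rng.choice(space.n_cells, size=6, replace=False))
            med = mg.medoid(space, subset)
            sums = {i: space.distances[np.ix_([i], subset)].sum() for i in subset}
            assert sums[med] == min(sums.values())


class TestAlignment:
    def test_identity_couplings_leave_unchanged(self):
        rng = np.random.default_rng(1)
        D = rng.random((5, 5))
        D = D + D.T
        np.fill_diagonal(D, 0)
        out = mg.align_to_medoid([D], [np.eye(5) / 5])
        assert np.array_equal(out[0], D)

    def test_permutation_coupling_conjugates(self):
        rng = np.random.default_rng(2)
        D = rng.random((4, 4))
        D = D + D.T
        np.fill_diagonal(D, 0)
        perm = np.array([2, 0, 3, 1])
        T = np.zeros((4, 4))
        T[np.arange(4), perm] = 0.25
        out = mg.align_to_medoid([D], [T])[0]
        assert np.array_equal(out, D[np.ix_(perm, perm)])

    def test_hardening_matches_exhaustive_assignment(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            T = rng.random((4, 4))
            T /= T.sum()
            perm = mg.harden_coupling(T)
            best = max(itertools.permutations(range(4)),
                       key=lambda pr: sum(T[i, pr[i]] for i in range(4)))
            assert sum(T[i, perm[i]] for i in range(4)) == pytest.approx(
                sum(T[i, best[i]] for i in range(4)))

    def test_degenerate_coupling_rejected(self):
        with pytest.raises(ValueError, match="cell x"):
            mg.align_to_medoid([np.zeros((2, 2))], [np.full((2, 2), np.nan)],
                               cell_ids=["x"])


class TestAverageMatrix:
    def test_identical_cells_identity_couplings(self, y_tree):
        cloud = mg.sample_swc_even(y_tree, 30)
        D = mg.geodesic_matrix_swc(y_tree, cloud).D
        aligned = mg.align_to_medoid([D] * 10, [np.eye(30) / 30] * 10)
        d_hat = mg.average_morphology_matrix(aligned, mode="transport")
        assert np.allclose(d_hat, D, atol=1e-12)

    def test_transport_average_nested_loop_oracle(self):
        """The one-sided coupling-weighted sum matches a direct nested-loop
        evaluation for hand-set permutation couplings."""
        rng = np.random.default_rng(4)
        mats, couplings = [], []
        n = 4
        for _ in range(2):
            D = rng.random((n, n))
            D = D + D.T
            np.fill_diagonal(D, 0)
            perm = rng.permutation(n)
            T = np.zeros((n, n))
            T[np.arange(n), perm] = 1.0 / n
            mats.append(D)
            couplings.append(T)
        got = mg.transport_average(mats, couplings, scale="raw")
        expect = np.zeros((n, n))
        for D, T in zip(mats, couplings):
            for a in range(n):
                for b in range(n):
                    for g in range(n):
                        expect[a, b] += T[a, g] * D[g, b]
        expect /= len(mats)
        assert np.allclose(got, expect, atol=1e-14)

    def test_thresholded_clip_rule(self):
        D = np.array([[0, 1, 2, 5],
                      [1, 0, 1, 2],
                      [2, 1, 0, 1],
                      [5, 2, 1, 0]], dtype=float)
        out = mg.average_morphology_matrix([D], mode="thresholded")
        assert np.array_equal(out, np.clip(D, 0, 2))

    def test_thresholded_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mg.average_morphology_matrix([np.zeros((3, 3))], mode="thresholded")


class TestShapeTree:
    def _thresholded(self, D):
        return np.clip(np.rint(D / D[D > 0].min()), 0, 2)

    def test_path_cell_gives_path(self, path_tree):
        cloud = mg.sample_swc_even(path_tree, 10)
        D = mg.geodesic_matrix_swc(path_tree, cloud).D
        _, spt, _, _ = mg.shape_tree(self._thresholded(D), mode="thresholded")
        assert set(map(tuple, spt.tolist())) == {(i, i + 1) for i in range(9)}

    def test_y_cluster_one_branch_point(self, y_tree):
        cloud = mg.sample_swc_even(y_tree, 30)
        D = mg.geodesic_matrix_swc(y_tree, cloud).D
        aligned = mg.align_to_medoid([D] * 10, [np.eye(30) / 30] * 10)
        d_hat = mg.average_morphology_matrix(aligned, mode="thresholded")
        _, spt, conf, conf_scaled = mg.shape_tree(d_hat, mode="thresholded")
        deg = np.bincount(spt.ravel(), minlength=30)
        assert (deg == 3).sum() == 1
        assert deg.max() == 3
        assert len(spt) == 29
        assert np.all(np.isfinite(conf))
        assert conf_scaled.min() == 0.0 and conf_scaled.max() == 1.0

    def test_spt_matches_independent_dijkstra(self):
        """Tree edges agree with a hand-rolled Dijkstra on the same graph."""
        rng = np.random.default_rng(6)
        pts = np.sort(rng.random(20))
        D = np.abs(pts[:, None] - pts[None, :])
        knn_edges, spt, _, _ = mg.shape_tree(D, mode="metric")
        # reference: dense Dijkstra from node 0 restricted to the kNN edges
        import heapq
        adj = {i: [] for i in range(20)}
        for i, j in knn_edges:
            w = max(D[i, j], 1e-12)
            adj[i].append((j, w))
            adj[j].append((i, w))
        dist = {0: 0.0}
        pred = {}
        heap = [(0.0, 0)]
        seen = set()
        while heap:
            d0, u = heapq.heappop(heap)
            if u in seen:
                continue
            seen.add(u)
            for v, w in adj[u]:
                nd = d0 + w
                if nd < dist.get(v, np.inf) - 1e-15:
                    dist[v] = nd
                    pred[v] = u
                    heapq.heappush(heap, (nd, v))
        expect = {(min(v, u), max(v, u)) for v, u in pred.items()}
        assert set(map(tuple, spt.tolist())) == expect


class TestClusterEmbed:
    def test_two_blobs_recovered(self, blob_space):
        space, labels = blob_space
        from sklearn.metrics import adjusted_rand_score
        lab = mg.cluster(space, k_graph=10, seed=5)
        assert adjusted_rand_score(labels, lab.labels) == 1.0

    def test_tiny_space(self):
        D = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        space = mg.GWSpace(cell_ids=list("abc"), distances=D)
        lab = mg.cluster(space, k_graph=2, seed=1)
        assert len(lab.labels) == 3

    def test_cluster_seed_reproducible(self, blob_space):
        space, _ = blob_space
        a = mg.cluster(space, seed=11)
        b = mg.cluster(space, seed=11)
        assert np.array_equal(a.labels, b.labels)

    def test_embedding_seeded_and_separates(self, blob_space):
        space, labels = blob_space
        from sklearn.metrics import silhouette_score
        e1 = mg.embed_2d(space, n_neighbors=10, seed=3)
        e2 = mg.embed_2d(space, n_neighbors=10, seed=3)
        assert np.array_equal(e1, e2)
        assert e1.shape == (space.n_cells, 2)
        assert silhouette_score(e1, labels) > 0.5

    def test_embedding_tiny_space(self):
        rng = np.random.default_rng(8)
        D = rng.random((5, 5))
        D = D + D.T
        np.fill_diagonal(D, 0)
        space = mg.GWSpace(cell_ids=[f"c{i}" for i in range(5)], distances=D)
        assert mg.embed_2d(space, seed=0).shape == (5, 2)
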