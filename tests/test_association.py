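"""Laplacian-score feature association: graph, score, permutation test."""

import numpy as np
import pandas as pd
import pytest

import morphgw as mg
from morphgw.association import benjamini_hochberg


@pytest.fixture
def small_space():
    D = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
    return mg.GWSpace(cell_ids=list("abc"), distances=D)


class TestRadiusGraph:
    def test_numeric_eps(self, small_space):
        g = mg.radius_graph(small_space, eps=1.5)
        assert g.A.sum() == 2  # single undirected edge a-b

    def test_median_eps(self, small_space):
        g = mg.radius_graph(small_space, eps="median")
        assert g.eps == 2.0
        assert g.A.sum() == 4  # edges at distances 1 and 2

    def test_huge_eps_complete_graph(self, small_space):
        g = mg.radius_graph(small_space, eps=100.0)
        N = 3
        assert g.A.sum() == N * (N - 1)

    def test_nonpositive_eps_rejected(self, small_space):
        with pytest.raises(ValueError):
            mg.radius_graph(small_space, eps=-1.0)


class TestLaplacianScore:
    def _graph(self):
        A = np.zeros((4, 4), dtype=int)
        A[0, 1] = A[1, 0] = 1
        A[2, 3] = A[3, 2] = 1
        return A

    def test_constant_on_components_scores_zero(self):
        assert mg.laplacian_score(np.array([0, 0, 1, 1.0]), self._graph()) == 0.0

    def test_alternating_feature(self):
        # ordered-pair sum 4, population variance 1/4
        assert mg.laplacian_score(np.array([0, 1, 0, 1.0]), self._graph()) == \
            pytest.approx(16.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        A = (rng.random((10, 10)) < 0.3).astype(int)
        A = np.triu(A, 1)
        A = A + A.T
        f = rng.normal(size=10)
        assert mg.laplacian_score(2 * f + 3, A) == pytest.approx(
            mg.laplacian_score(f, A), rel=1e-12)

    def test_matches_nested_loop_oracle(self):
        """Score equals the direct ordered-pair sum over random graphs."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            N = int(rng.integers(4, 15))
            A = (rng.random((N, N)) < 0.4).astype(int)
            A = np.triu(A, 1)
            A = A + A.T
            f = rng.normal(size=N)
            direct = sum((f[i] - f[j]) ** 2 * A[i, j]
                         for i in range(N) for j in range(N))
            direct /= f.var()
            assert mg.laplacian_score(f, A) == pytest.approx(direct, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            mg.laplacian_score(np.ones(4), self._graph())


class TestPermutationTest:
    @pytest.fixture
    def graph(self, blob_space):
        space, _ = blob_space
        return mg.radius_graph(space, eps="median")

    def test_seeded_reproducibility(self, graph):
        f = pd.DataFrame({"g": np.random.default_rng(3).normal(size=40)})
        a = mg.permutation_test(f, graph, n_perm=200, seed=9)
        b = mg.permutation_test(f, graph, n_perm=200, seed=9)
        assert np.array_equal(a.table["p"], b.table["p"])

    def test_column_order_invariance(self, graph, blob_space):
        _, labels = blob_space
        rng = np.random.default_rng(5)
        f = pd.DataFrame({
            "planted": labels + 0.3 * rng.normal(size=40),
            "noise": rng.normal(size=40),
        })
        a = mg.permutation_test(f, graph, n_perm=200, seed=1)
        b = mg.permutation_test(f[["noise", "planted"]], graph, n_perm=200, seed=1)
        ta = a.table.set_index("feature")
        tb = b.table.set_index("feature")
        assert ta.loc["planted", "p"] == tb.loc["planted", "p"]
        assert ta.loc["noise", "p"] == tb.loc["noise", "p"]

    def test_consistent_relabeling_invariance(self, blob_space):
        """Permuting cells in both the graph and the features leaves the
        observed scores unchanged."""
        space, labels = blob_space
        graph = mg.radius_graph(space, eps="median")
        rng = np.random.default_rng(6)
        f = pd.DataFrame({"g": labels + 0.5 * rng.normal(size=40)})
        perm = rng.permutation(40)
        A2 = graph.A[np.ix_(perm, perm)]
        f2 = f.iloc[perm].reset_index(drop=True)
        a = mg.laplacian_score(f["g"].to_numpy(), graph.A)
        b = mg.laplacian_score(f2["g"].to_numpy(), A2)
        assert a == pytest.approx(b, rel=1e-12)

    def test_planted_community_significant(self, blob_space):
        space, labels = blob_space
        graph = mg.radius_graph(space, eps="median")
        f = pd.DataFrame({"ind": (labels == 0).astype(float)})
        res = mg.permutation_test(f, graph, n_perm=1000, seed=2)
        assert res.table["p"].iloc[0] <= 0.01

    def test_feature_equal_to_covariate_absorbed(self, blob_space):
        space, labels = blob_space
        graph = mg.radius_graph(space, eps="median")
        cov = pd.DataFrame({"c": labels.astype(float)})
        f = pd.DataFrame({"g": labels.astype(float)})
        res = mg.permutation_test(f, graph, covariates=cov, n_perm=500, seed=3)
        assert res.table["p"].iloc[0] > 0.2

    def test_too_few_permutations_rejected(self, graph):
        f = pd.DataFrame({"g": np.arange(40, dtype=float)})
        with pytest.raises(ValueError, match="n_perm"):
            mg.permutation_test(f, graph, n_perm=50, seed=0)

    def test_constant_covariate_rejected(self, graph):
        f = pd.DataFrame({"g": np.arange(40, dtype=float)})
        cov = pd.DataFrame({"c": np.ones(40)})
        with pytest.raises(ValueError, match="covariate"):
            mg.permutation_test(f, graph, covariates=cov, n_perm=200, seed=0)


class TestPrepareExpression:
    def test_normalization_values(self):
        counts = pd.DataFrame(
            {"g1": [1, 4], "g2": [99, 196]}, index=["cellA", "cellB"])
        out, report = mg.prepare_expression(counts, min_detect=0.0, max_detect=1.1)
        assert out.loc["cellA", "g1"] == pytest.approx(np.log(1 + 50))
        assert out.loc["cellB", "g1"] == pytest.approx(np.log(1 + 100))

    def test_detection_band(self):
        n = 100
        rare = np.zeros(n); rare[:4] = 1.0          # 4% -> dropped
        ok = np.zeros(n); ok[:50] = 1.0             # 50% -> kept
        counts = pd.DataFrame({
            "rare": rare,
            "ok": ok,
            "ubiquitous": np.ones(n),               # 100% -> dropped
            "filler": np.ones(n),                   # keeps totals > 0
        })
        out, report = mg.prepare_expression(counts)
        kept = set(out.columns)
        assert "ok" in kept
        assert "rare" not in kept and "ubiquitous" not in kept
        assert report.set_index("gene").loc["rare", "kept"] == False  # noqa: E712

    def test_zero_total_cell_rejected(self):
        counts = pd.DataFrame({"g1": [0, 1], "g2": [0, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="zero total"):
            mg.prepare_expression(counts)


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        p = rng.random(50)
        q = benjamini_hochberg(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_ref, atol=1e-12)
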