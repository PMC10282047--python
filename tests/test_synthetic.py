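"""Synthetic generators: trees, deformations, feature tables."""

import numpy as np
import pytest

import morphgw as mg
from morphgw.synthetic import (
    NeuronClassSpec, PlantedFeatureSpec, bend_tree, generate_features,
    generate_neuron, generate_population, rigid_transform,
)


class TestGenerateNeuron:
    def test_unbranched_is_straight_path(self):
        spec = NeuronClassSpec(n_branches=0, branch_length_mean=10.0,
                               branch_length_sd=0.0, branch_angle_sd=0.0,
                               segment_step=2.0, seed=0)
        tree = generate_neuron(spec)
        assert tree.total_length() == pytest.approx(10.0, abs=1e-9)
        d = np.diff(tree.xyz, axis=0)
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        assert np.allclose(d, d[0])  # collinear

    def test_seed_determinism_bytes(self, tmp_path):
        spec = NeuronClassSpec(n_branches=4, seed=5)
        a, b = tmp_path / "a.swc", tmp_path / "b.swc"
        mg.write_swc(generate_neuron(spec), a)
        mg.write_swc(generate_neuron(spec), b)
        assert a.read_bytes() == b.read_bytes()

    def test_output_readable_and_valid(self, tmp_path):
        spec = NeuronClassSpec(n_branches=6, seed=9)
        path = tmp_path / "n.swc"
        mg.write_swc(generate_neuron(spec), path)
        tree = mg.read_swc(path)
        assert tree.total_length() > 0

    def test_branch_count_scales_nodes(self):
        t2 = generate_neuron(NeuronClassSpec(n_branches=2, seed=1))
        t8 = generate_neuron(NeuronClassSpec(n_branches=8, seed=1))
        assert t8.n_nodes > t2.n_nodes

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            NeuronClassSpec(segment_step=-1.0)

    def test_population_labels(self):
        specs = [NeuronClassSpec(n_branches=2, seed=0),
                 NeuronClassSpec(n_branches=8, seed=0)]
        trees, labels = generate_population(specs, 3, seed=4)
        assert len(trees) == 6
        assert np.array_equal(labels, [0, 0, 0, 1, 1, 1])


class TestRigidTransform:
    def test_preserves_euclidean_matrix(self):
        tree = generate_neuron(NeuronClassSpec(n_branches=3, seed=2))
        cloud = mg.sample_swc_even(tree, 30)
        moved = rigid_transform(cloud, seed=8)
        D1 = mg.euclidean_matrix(cloud).D
        D2 = mg.euclidean_matrix(moved).D
        assert np.allclose(D1, D2, atol=1e-12 * max(1.0, D1.max()))

    def test_reflection_preserves_matrix(self):
        tree = generate_neuron(NeuronClassSpec(n_branches=3, seed=2))
        cloud = mg.sample_swc_even(tree, 30)
        refl = rigid_transform(cloud, seed=8, reflect=True)
        assert np.allclose(mg.euclidean_matrix(cloud).D,
                           mg.euclidean_matrix(refl).D, atol=1e-10)

    def test_composition_still_isometric(self):
        tree = generate_neuron(NeuronClassSpec(n_branches=3, seed=2))
        cloud = mg.sample_swc_even(tree, 30)
        twice = rigid_transform(rigid_transform(cloud, seed=1), seed=2)
        assert np.allclose(mg.euclidean_matrix(cloud).D,
                           mg.euclidean_matrix(twice).D, atol=1e-10)


class TestBendTree:
    def test_zero_angle_identity(self, y_tree):
        bent = bend_tree(y_tree, joint=2, angle=0.0, seed=0)
        assert np.allclose(bent.xyz, y_tree.xyz, atol=1e-12)

    def test_l_bend_of_path(self):
        tree = mg.NeuronTree(node_ids=[1, 2, 3], structure=[1, 3, 3],
                             xyz=[[0, 0, 0], [1, 0, 0], [2, 0, 0]],
                             radius=[1] * 3, parent=[-1, 0, 1])
        bent = bend_tree(tree, joint=1, angle=np.pi / 2, axis=[0, 0, 1])
        c0 = mg.sample_swc_even(tree, 3)
        c1 = mg.sample_swc_even(bent, 3)
        g0 = mg.geodesic_matrix_swc(tree, c0).D
        g1 = mg.geodesic_matrix_swc(bent, c1).D
        assert np.allclose(g0, g1, atol=1e-9)
        e0 = mg.euclidean_matrix(c0).D
        e1 = mg.euclidean_matrix(c1).D
        assert e1[0, 2] < e0[0, 2] - 0.1

    def test_geodesic_matrix_exactly_preserved(self):
        tree = generate_neuron(NeuronClassSpec(n_branches=5, seed=6))
        cloud = mg.sample_swc_even(tree, 40)
        g0 = mg.geodesic_matrix_swc(tree, cloud).D
        for k, (joint, angle) in enumerate([(5, 0.5), (12, 1.2), (20, -0.9)]):
            bent = bend_tree(tree, joint=joint, angle=angle, seed=k)
            g1 = mg.geodesic_matrix_swc(bent, mg.sample_swc_even(bent, 40)).D
            assert np.allclose(g0, g1, atol=1e-9)


class TestGenerateFeatures:
    def test_truth_bookkeeping(self):
        labels = np.repeat([0, 1], 20)
        spec = PlantedFeatureSpec(n_cells=40, n_features=10, n_localized=3,
                                  n_confounded=2, seed=0)
        feats, cov, truth = generate_features(labels, spec)
        assert feats.shape == (40, 10)
        assert len(truth["localized"]) == 3
        assert len(truth["confounded"]) == 2
        assert list(cov.columns) == ["age"]
        assert set(np.unique(cov["age"])) <= {1, 2, 3, 4, 5}

    def test_strength_zero_gives_pure_noise(self):
        labels = np.repeat([0, 1], 20)
        spec = PlantedFeatureSpec(n_cells=40, n_features=5, n_localized=5,
                                  strength=0.0, seed=1)
        feats, _, _ = generate_features(labels, spec)
        # no mean shift between communities beyond sampling noise
        shift = feats[labels == 0].mean() - feats[labels == 1].mean()
        assert np.all(np.abs(shift) < 1.0)

    def test_seed_determinism(self):
        labels = np.repeat([0, 1], 20)
        spec = PlantedFeatureSpec(n_cells=40, seed=3)
        a, _, _ = generate_features(labels, spec)
        b, _, _ = generate_features(labels, spec)
        assert a.equals(b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            generate_features(np.zeros(10), PlantedFeatureSpec(n_cells=40))
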