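"""Centroid size, reflection-relabeling, GPA with object symmetry, tangent PCA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from morphoqtl.morphometrics import (
    LandmarkSet,
    SymmetryMap,
    centroid_size,
    generalized_procrustes,
    gpa_object_symmetry,
    landmark_repeatability,
    reflect_relabel,
    symmetric_component,
    tangent_pca,
    tangent_project,
)
from morphoqtl.simulate import make_base_configuration


def _random_landmarks(n, k, rng, scale=1.0):
    return rng.standard_normal((n, k, 3)) * scale


class TestCentroidSize:
    def test_unit_octahedron(self):
        config = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        assert centroid_size(config) == pytest.approx(np.sqrt(6))

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        config = rng.standard_normal((10, 3))
        assert centroid_size(config + np.array([10.0, -3.0, 7.0])) == pytest.approx(
            centroid_size(config)
        )

    def test_homogeneity(self):
        rng = np.random.default_rng(1)
        config = rng.standard_normal((8, 3))
        assert centroid_size(config * 2.5) == pytest.approx(2.5 * centroid_size(config))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        config = rng.standard_normal((12, 3))
        R = Rotation.random(rng=rng).as_matrix()
        assert centroid_size(config @ R.T + 4.2) == pytest.approx(centroid_size(config))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            centroid_size(np.array([[np.nan, 0, 0]]))


class TestReflectRelabel:
    sym = SymmetryMap(pairs=[(0, 1)], midline=[2])

    def test_symmetric_config_fixed(self):
        config = np.array([[1.0, 0.5, -0.2], [-1.0, 0.5, -0.2], [0.0, 1.0, 1.0]])
        assert np.allclose(reflect_relabel(config, self.sym), config)

    def test_involution(self):
        rng = np.random.default_rng(3)
        config = rng.standard_normal((3, 3))
        out = reflect_relabel(reflect_relabel(config, self.sym), self.sym)
        assert np.array_equal(out, config)

    def test_single_pair_hand_case(self):
        sym = SymmetryMap(pairs=[(0, 1)], midline=[])
        config = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
        assert np.allclose(reflect_relabel(config, sym), config)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reflect_relabel(np.zeros((5, 3)), self.sym)

    def test_overlapping_map_rejected(self):
        with pytest.raises(ValueError):
            SymmetryMap(pairs=[(0, 1)], midline=[1])


class TestGeneralizedProcrustes:
    def test_rigid_motions_align_exactly(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal((10, 3))
        configs = []
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            configs.append(base @ R.T * rng.uniform(0.5, 2.0) + rng.uniform(-5, 5, 3))
        aligned, consensus = generalized_procrustes(np.asarray(configs))
        assert np.var(aligned, axis=0).sum() < 1e-12

    def test_known_rotations_recovered(self):
        rng = np.random.default_rng(5)
        n, k = 12, 9
        shapes = rng.standard_normal((1, k, 3)) + 0.01 * rng.standard_normal((n, k, 3))
        ref_aligned, _ = generalized_procrustes(shapes.copy())
        nuisance = shapes.copy()
        for i in range(n):
            R = Rotation.random(rng=rng).as_matrix()
            nuisance[i] = nuisance[i] @ R.T * rng.uniform(0.5, 2) + rng.uniform(-3, 3, 3)
        aligned, _ = generalized_procrustes(nuisance)
        # same shapes up to the group action: pairwise shape distances agree
        d_ref = np.linalg.norm(ref_aligned[:, None] - ref_aligned[None], axis=(2, 3))
        d_new = np.linalg.norm(aligned[:, None] - aligned[None], axis=(2, 3))
        assert np.abs(d_ref - d_new).max() < 1e-8

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            generalized_procrustes(np.zeros((3, 5, 3)))


class TestObjectSymmetry:
    def _sample(self, n=40, noise=0.005, seed=6, pairs=5, midline=3):
        rng = np.random.default_rng(seed)
        base, sym = make_base_configuration(pairs, midline, seed=seed)
        coords = base[None] + noise * rng.standard_normal((n, base.shape[0], 3))
        for i in range(n):
            R = Rotation.random(rng=rng).as_matrix()
            coords[i] = coords[i] @ R.T * rng.uniform(0.8, 1.2) + rng.uniform(-2, 2, 3)
        data = LandmarkSet([f"s{i}" for i in range(n)],
                           [f"L{j}" for j in range(base.shape[0])], coords)
        return data, sym

    def test_symmetric_sample_has_no_asymmetry(self):
        rng = np.random.default_rng(7)
        base, sym = make_base_configuration(4, 3, seed=7)
        k = base.shape[0]
        # perturb only within the symmetric subspace
        from morphoqtl.simulate import symmetric_tangent_basis

        basis = symmetric_tangent_basis(base, sym)
        coords = np.array([
            base + (0.01 * rng.standard_normal(basis.shape[0]) @ basis).reshape(k, 3)
            for _ in range(10)
        ])
        data = LandmarkSet([f"s{i}" for i in range(10)], [f"L{j}" for j in range(k)], coords)
        space = gpa_object_symmetry(data, sym)
        assert np.abs(space.asymmetric).max() < 1e-10

    def test_consensus_is_symmetric(self):
        data, sym = self._sample()
        space = gpa_object_symmetry(data, sym)
        assert np.abs(reflect_relabel(space.consensus, sym) - space.consensus).max() < 1e-8

    def test_dimension_law(self):
        # retained PCs = 3p + 2l - 4 for generic data
        for p, l in [(5, 3), (3, 4)]:
            data, sym = self._sample(n=60, pairs=p, midline=l, seed=10 + p)
            space = gpa_object_symmetry(data, sym)
            assert space.q == 3 * p + 2 * l - 4

    def test_rank_bound_small_n(self):
        data, sym = self._sample(n=3, seed=11)
        space = gpa_object_symmetry(data, sym)
        assert space.q <= 2

    def test_scores_reproduce_tangent_coordinates(self):
        data, sym = self._sample()
        space = gpa_object_symmetry(data, sym)
        flat = space.symmetric.reshape(space.n, -1)
        tang = tangent_project(flat, space.consensus.ravel())
        recon = space.scores @ space.basis + space.mean_tangent
        assert np.abs(recon - tang).max() < 1e-9

    def test_basis_orthonormal_and_eigenvalues_sorted(self):
        data, sym = self._sample()
        space = gpa_object_symmetry(data, sym)
        q = space.q
        assert np.abs(space.basis @ space.basis.T - np.eye(q)).max() < 1e-10
        assert np.all(np.diff(space.eigenvalues) <= 0)
        assert np.all(space.eigenvalues >= 0)

    def test_symmetric_asymmetric_orthogonal_decomposition(self):
        # the split is an exact even/odd decomposition under reflection:
        # components are pointwise orthogonal and reproduce the aligned data
        data, sym = self._sample(n=80, seed=12)
        space = gpa_object_symmetry(data, sym)
        assert np.abs(reflect_relabel(space.symmetric, sym) - space.symmetric).max() < 1e-12
        assert np.abs(reflect_relabel(space.asymmetric, sym) + space.asymmetric).max() < 1e-12
        s = space.symmetric.reshape(space.n, -1)
        a = space.asymmetric.reshape(space.n, -1)
        sc, ac = s - s.mean(0), a - a.mean(0)
        dots = np.abs((sc * ac).sum(axis=1))
        assert dots.max() < 1e-12


class TestSymmetricComponent:
    def test_planted_asymmetry_recovered(self):
        rng = np.random.default_rng(13)
        orig = rng.standard_normal((6, 3))
        delta = np.zeros((6, 3))
        delta[2] = [0.1, -0.05, 0.02]
        refl = orig - delta  # pretend aligned reflected copy
        sym_c, asym_c = symmetric_component(orig, refl)
        assert np.allclose(asym_c, delta / 2)
        assert np.allclose(sym_c, orig - delta / 2)

    def test_frame_mismatch_rejected(self):
        with pytest.raises(ValueError):
            symmetric_component(np.zeros((5, 3)), np.zeros((4, 3)))


class TestTangentPCA:
    def test_plain_gpa_dimension(self):
        # without symmetry processing a generic sample spans 3k - 7 dimensions
        rng = np.random.default_rng(14)
        k, n = 8, 120
        configs = rng.standard_normal((1, k, 3)) + 0.01 * rng.standard_normal((n, k, 3))
        aligned, consensus = generalized_procrustes(configs)
        tang = tangent_project(aligned.reshape(n, -1), consensus.ravel())
        scores, basis, lam, mean = tangent_pca(tang)
        assert scores.shape[1] == 3 * k - 7

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            tangent_pca(np.random.default_rng(0).standard_normal((5, 9)), tol=0.0)


class TestRepeatability:
    def _replicates(self, offset_landmark=None, offset=0.0):
        rng = np.random.default_rng(15)
        a = rng.standard_normal((20, 6, 3))
        b = a.copy()
        if offset_landmark is not None:
            b[:, offset_landmark, 0] += offset
        names = [f"L{j}" for j in range(6)]
        ids = [f"s{i}" for i in range(20)]
        return (LandmarkSet(ids, names, a), LandmarkSet(ids, names, b))

    def test_identical_replicates(self):
        a, b = self._replicates()
        table, drop = landmark_repeatability(a, b, cutoff=0.125)
        assert drop == [] and table["median_error_mm"].max() == 0.0

    def test_offending_landmark_flagged(self):
        a, b = self._replicates(offset_landmark=3, offset=0.2)
        _, drop = landmark_repeatability(a, b, cutoff=0.125)
        assert drop == ["L3"]

    def test_small_offsets_pass(self):
        a, b = self._replicates(offset_landmark=3, offset=0.05)
        _, drop = landmark_repeatability(a, b, cutoff=0.125)
        assert drop == []

    def test_specimen_mismatch_rejected(self):
        a, b = self._replicates()
        b = LandmarkSet(["other", *b.specimens[1:]], b.landmarks, b.coords)
        with pytest.raises(ValueError):
            landmark_repeatability(a, b, cutoff=0.1)
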