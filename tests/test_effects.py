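"""Effect magnitudes, variance accounting, region decomposition, PC angles."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_scan_bundle
from morphoqtl.effects import (
    effect_magnitude,
    flag_against_null,
    pc_angle_analysis,
    projection_scores,
    random_vector_intervals,
    region_decomposition,
    variance_accounting,
)
from morphoqtl.morphometrics import RegionMap
from morphoqtl.multiqtl import Locus, fit_qtl_model


class TestMagnitude:
    def test_zero_and_unit(self):
        assert effect_magnitude(np.zeros(5)) == 0.0
        e = np.zeros(7); e[3] = 1.0
        assert effect_magnitude(e) == 1.0

    def test_orthonormal_basis_invariance(self):
        rng = np.random.default_rng(0)
        beta = rng.standard_normal(12)
        basis = np.linalg.qr(rng.standard_normal((20, 12)))[0].T  # 12 x 20 orthonormal rows
        assert abs(effect_magnitude(beta) - effect_magnitude(beta @ basis)) < 1e-10


def _fitted_single_qtl(small_backcross, rng_seed=1, q=4, noise=1.0):
    rng = np.random.default_rng(rng_seed)
    sb = small_backcross
    beta = np.zeros(q); beta[0] = 2.0
    Y = noise * rng.standard_normal((200, q)) + np.outer(sb["hidden_q"][:, 0] - 0.5, beta)
    data = make_scan_bundle(sb["probs"], Y)
    locus = Locus("2", 21.0)
    return data, fit_qtl_model(data, [locus]), locus, beta


class TestVarianceAccounting:
    def test_dominant_term_near_total(self, small_backcross):
        data, fit, locus, _ = _fitted_single_qtl(small_backcross, noise=0.01)
        va = variance_accounting(fit, data)
        pct = va.set_index("term")["pct_total_procrustes_variance"]
        assert pct[str(locus)] > 95.0

    def test_orthogonal_terms_sum_to_total(self):
        # orthogonal regressors decompose the total SS exactly
        rng = np.random.default_rng(2)
        n, q = 64, 3
        g1 = np.kron([1.0, -1.0], np.ones(32))
        g2 = np.kron([1.0, -1.0, 1.0, -1.0], np.ones(16))
        Y = np.outer(g1, rng.standard_normal(q)) + np.outer(g2, rng.standard_normal(q))
        grid = pd.DataFrame({"chrom": ["1", "1"], "pos_cM": [0.0, 1.0],
                             "is_marker": [True, True], "marker": ["a", "b"]})
        probs = type("P", (), {"grid": grid, "het": np.column_stack([g1, g2])})()
        data = make_scan_bundle(probs, Y)
        fit = fit_qtl_model(data, [Locus("1", 0.0), Locus("1", 1.0)])
        va = variance_accounting(fit, data)
        assert va["pct_total_procrustes_variance"].sum() == pytest.approx(100.0, abs=1e-8)

    def test_planted_one_percent_effect_estimated_in_band(self, small_backcross):
        rng = np.random.default_rng(3)
        sb = small_backcross
        q = 10
        m = np.sqrt(0.01 * q / 0.25 / 0.99)
        estimates = []
        for rep in range(20):
            beta = rng.standard_normal(q); beta *= m / np.linalg.norm(beta)
            Y = rng.standard_normal((200, q)) + np.outer(sb["hidden_q"][:, 0] - 0.5, beta)
            data = make_scan_bundle(sb["probs"], Y)
            fit = fit_qtl_model(data, [Locus("2", 21.0)])
            va = variance_accounting(fit, data).set_index("term")
            estimates.append(va.loc["2@21", "pct_total_procrustes_variance"])
        assert 0.5 <= np.mean(estimates) <= 2.0


class TestProjectionScores:
    def test_exact_effect_gives_full_percentage(self):
        rng = np.random.default_rng(4)
        n, q = 80, 5
        g = rng.integers(0, 2, n).astype(float)
        beta = rng.standard_normal(q)
        Y = np.outer(g, beta)
        grid = pd.DataFrame({"chrom": ["1"], "pos_cM": [0.0],
                             "is_marker": [True], "marker": ["a"]})
        probs = type("P", (), {"grid": grid, "het": g[:, None]})()
        data = make_scan_bundle(probs, Y)
        fit = fit_qtl_model(data, [Locus("1", 0.0)])
        s, pct = projection_scores(Y, beta, data, fit, "1@0")
        assert pct == pytest.approx(100.0, abs=1e-8)

    def test_orthogonal_response_zero_scores(self):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((30, 4))
        beta = np.zeros(4); beta[0] = 1.0
        Y[:, 0] = 0.0
        s, _ = projection_scores(Y, beta)
        assert np.allclose(s, 0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            projection_scores(np.ones((5, 3)), np.zeros(3))


class TestRegionDecomposition:
    rmap = RegionMap({0: ("A",), 1: ("A",), 2: ("B",), 3: ("A", "B")})

    def test_single_region_displacement(self):
        disp = np.zeros((4, 3))
        disp[0] = [1.0, 0, 0]
        dec = region_decomposition(disp, self.rmap).set_index("region")
        assert dec.loc["A", "raw_proportion"] == 1.0
        assert dec.loc["B", "raw_proportion"] == 0.0

    def test_boundary_landmark_split_equally(self):
        disp = np.zeros((4, 3))
        disp[3] = [0.0, 2.0, 0.0]
        dec = region_decomposition(disp, self.rmap).set_index("region")
        assert dec.loc["A", "raw_proportion"] == pytest.approx(0.5)
        assert dec.loc["B", "raw_proportion"] == pytest.approx(0.5)

    def test_equal_magnitudes_closed_form(self):
        disp = np.zeros((4, 3))
        disp[:, 0] = 1.0
        dec = region_decomposition(disp, self.rmap).set_index("region")
        # fractional counts: A = 2.5, B = 1.5 of 4 landmarks
        assert dec.loc["A", "raw_proportion"] == pytest.approx(2.5 / 4)
        assert dec.loc["B", "raw_proportion"] == pytest.approx(1.5 / 4)
        assert np.allclose(dec["normalized_proportion"], 0.5)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(6)
        disp = rng.standard_normal((4, 3))
        dec = region_decomposition(disp, self.rmap)
        assert dec["raw_proportion"].sum() == pytest.approx(1.0, abs=1e-12)
        assert dec["normalized_proportion"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_displacement_rejected(self):
        with pytest.raises(ValueError):
            region_decomposition(np.zeros((4, 3)), self.rmap)


class TestRandomVectorIntervals:
    @pytest.fixture(scope="class")
    def shape_space(self):
        from morphoqtl.morphometrics import LandmarkSet, gpa_object_symmetry
        from morphoqtl.simulate import default_region_map, make_base_configuration
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(7)
        base, sym = make_base_configuration(8, 5, seed=7)
        n, k = 60, base.shape[0]
        coords = base[None] + 0.01 * rng.standard_normal((n, k, 3))
        for i in range(n):
            coords[i] = coords[i] @ Rotation.random(rng=rng).as_matrix().T
        data = LandmarkSet([f"s{i}" for i in range(n)], [f"L{j}" for j in range(k)], coords)
        return gpa_object_symmetry(data, sym), default_region_map(8, 5), sym

    def test_seed_determinism(self, shape_space):
        space, regions, _ = shape_space
        a = random_vector_intervals(space, regions, n_draws=200, seed=3)
        b = random_vector_intervals(space, regions, n_draws=200, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_interval_midpoints_converge(self, shape_space):
        space, regions, _ = shape_space
        small = random_vector_intervals(space, regions, n_draws=200, seed=4)
        large = random_vector_intervals(space, regions, n_draws=3000, seed=5)
        # interval widths shrink-stabilize and means stay consistent
        assert np.abs(small["raw_mean"] - large["raw_mean"]).max() < 0.05

    def test_targeted_effect_flagged(self, shape_space):
        space, regions, sym = shape_space
        rng = np.random.default_rng(8)
        # displacement confined to neurocranium landmarks, symmetric subspace
        from morphoqtl.simulate import _region_direction, symmetric_tangent_basis

        basis = symmetric_tangent_basis(space.consensus, sym)
        u = _region_direction(("neurocranium",), regions, basis, space.k, rng)
        disp = (u @ basis).reshape(space.k, 3)
        dec = region_decomposition(disp, regions)
        null = random_vector_intervals(space, regions, n_draws=500, seed=9)
        flags = flag_against_null(dec, null).set_index("region")
        assert bool(flags.loc["neurocranium", "raw_above"])


class TestPCAngles:
    def test_effect_equal_to_pc1(self):
        beta = np.zeros(10); beta[0] = 2.0
        out = pc_angle_analysis([beta], 10, mode="pc1", n_null=500, n_shuffle=10, seed=0)
        assert out["angles_deg"][0] == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_to_subspace(self):
        beta = np.zeros(10); beta[7] = 1.0
        out = pc_angle_analysis([beta], 10, mode="subspace", k=5, n_null=500,
                                n_shuffle=10, seed=0)
        assert out["angles_deg"][0] == pytest.approx(90.0)

    def test_isotropic_null_matches_analytic_moment(self):
        # for isotropic vectors in q dims, E[cos^2 theta to a fixed axis] = 1/q
        q = 80
        rng = np.random.default_rng(10)
        vs = rng.standard_normal((4000, q))
        cos2 = vs[:, 0] ** 2 / (vs**2).sum(axis=1)
        se = cos2.std() / np.sqrt(len(cos2))
        assert abs(cos2.mean() - 1 / q) < 3 * se
        out = pc_angle_analysis([np.ones(q)], q, mode="pc1", n_null=4000,
                                n_shuffle=10, seed=11)
        # the function's null mean angle matches the folded-angle expectation
        expected_angle = np.degrees(np.arccos(np.sqrt(cos2))).mean()
        assert abs(out["null_mean_angle_deg"] - expected_angle) < 0.5

    def test_aligned_effects_significant(self):
        rng = np.random.default_rng(12)
        q = 40
        betas = [np.concatenate([rng.standard_normal(3), 0.05 * rng.standard_normal(q - 3)])
                 for _ in range(8)]
        out = pc_angle_analysis(betas, q, mode="subspace", k=3, n_null=2000,
                                n_shuffle=200, seed=13)
        assert out["p_mean_angle_smaller"] < 0.01
        assert np.all(out["angles_deg"] >= 0) and np.all(out["angles_deg"] <= 90)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            pc_angle_analysis([np.ones(5)], 5, mode="nope")
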