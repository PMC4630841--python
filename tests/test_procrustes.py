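"""Superimposition: centroid size, alignment, GPA, symmetry, distances."""

import numpy as np
import pytest

from conftest import brute_force_procrustes_distance, make_dataset, random_rotation
from morphotraj.procrustes import (
    align_to,
    centroid_size,
    gpa,
    gpa_with_object_symmetry,
    procrustes_distance,
    reflect_relabel,
)
from morphotraj.simulate import make_symmetric_mean, symmetrize


class TestCentroidSize:
    def test_analytic_square(self):
        config = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
        assert centroid_size(config) == pytest.approx(np.sqrt(8))

    def test_coincident_landmarks_give_zero(self):
        assert centroid_size(np.ones((5, 3))) == 0.0

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(0)
        config = rng.normal(size=(7, 3))
        assert centroid_size(3.5 * config) == pytest.approx(
            3.5 * centroid_size(config))

    def test_missing_values_rejected(self):
        config = np.zeros((4, 3))
        config[1, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            centroid_size(config)


class TestAlignTo:
    def test_rotated_copy_residual_zero(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(8, 3))
        config = ref @ random_rotation(rng).T + rng.normal(size=3)
        _, residual = align_to(config, ref)
        assert residual < 1e-20

    def test_mirror_image_needs_reflection(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(8, 3))
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        _, res_no = align_to(mirrored, ref, allow_reflection=False)
        _, res_yes = align_to(mirrored, ref, allow_reflection=True)
        assert res_no > 1e-4
        assert res_yes < 1e-20

    def test_degenerate_configuration_rejected(self):
        line = np.zeros((5, 3))
        line[:, 0] = np.arange(5)
        with pytest.raises(ValueError, match="rank"):
            align_to(line, line)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_rotation_grid_oracle_on_triangles(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(3, 3))
        b = rng.normal(size=(3, 3))
        _, residual = align_to(a, b)
        oracle = brute_force_procrustes_distance(a, b)
        assert np.sqrt(residual) == pytest.approx(oracle, abs=1e-4)


class TestGPA:
    def test_identical_shapes_align_exactly(self, mandible_template):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(9, 3))
        stack = []
        for _ in range(5):
            motion = base @ random_rotation(rng).T * rng.uniform(0.5, 2.0)
            stack.append(motion + rng.normal(size=3))
        result = gpa(make_dataset(mandible_template, np.stack(stack)))
        assert result.ss_trace[-1] < 1e-18
        spread = result.aligned - result.aligned[0]
        assert np.abs(spread).max() < 1e-9

    def test_ss_descent_is_monotone(self, mandible_template):
        rng = np.random.default_rng(7)
        stack = rng.normal(size=(12, 9, 3)) + 4 * rng.normal(size=(1, 9, 3))
        result = gpa(make_dataset(mandible_template, stack))
        assert result.converged
        assert np.all(np.diff(result.ss_trace) <= 1e-12)
        assert result.iterations < 20

    def test_two_shape_total_ss_matches_joint_optimisation_oracle(self):
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(2, 6, 3))
        result = gpa(np.stack([a, b]))

        def standardise(x):
            x = x - x.mean(axis=0)
            return x / np.sqrt((x**2).sum())

        sa, sb = standardise(a), standardise(b)

        def objective(angles):
            # joint objective: min over rotations and unit-size consensus of
            # sum_i ||y_i R_i - c||^2 = 4 - 2 ||y_1 + y_2 R||  (R_1 fixed by
            # global rotation invariance, c = rescaled mean)
            rot = Rotation.from_euler("zyx", angles).as_matrix()
            return 4.0 - 2.0 * np.linalg.norm(sa + sb @ rot)

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-12, "fatol": 1e-15}).fun
            for x0 in ([0.1, 0.2, 0.3], [2.0, -1.0, 0.5], [-2.0, 1.0, 2.5])
        )
        assert result.ss_trace[-1] == pytest.approx(best, rel=1e-6)

    def test_rigid_motion_invariance(self, mandible_template):
        rng = np.random.default_rng(9)
        stack = rng.normal(size=(6, 9, 3))
        result1 = gpa(make_dataset(mandible_template, stack))
        moved = np.stack([
            c @ random_rotation(rng).T * rng.uniform(0.2, 5.0)
            + rng.normal(size=3)
            for c in stack
        ])
        result2 = gpa(make_dataset(mandible_template, moved))
        # Procrustes distances between aligned specimens are frame-free
        d1 = [procrustes_distance(result1.aligned[i], result1.aligned[j])
              for i in range(6) for j in range(i)]
        d2 = [procrustes_distance(result2.aligned[i], result2.aligned[j])
              for i in range(6) for j in range(i)]
        np.testing.assert_allclose(d1, d2, atol=1e-8)

    def test_specimen_order_invariance(self, mandible_template):
        rng = np.random.default_rng(10)
        stack = rng.normal(size=(7, 9, 3))
        result = gpa(make_dataset(mandible_template, stack))
        perm = rng.permutation(7)
        result_p = gpa(make_dataset(mandible_template, stack[perm]))
        for i, pi in enumerate(perm):
            assert procrustes_distance(
                result.aligned[pi], result_p.aligned[i]) < 1e-9


class TestObjectSymmetry:
    def _symmetric_dataset(self, template, n, noise, seed, asym=0.0):
        rng = np.random.default_rng(seed)
        base = make_symmetric_mean(template, seed=seed)
        stack = []
        for _ in range(n):
            shape = base + noise * rng.normal(size=base.shape)
            shape = symmetrize(shape, template)
            if asym:
                shape = shape + asym * rng.normal(size=base.shape)
            shape = shape @ random_rotation(rng).T + rng.normal(size=3)
            stack.append(shape)
        return make_dataset(template, np.stack(stack))

    def test_symmetric_specimens_have_no_asymmetry(self, cranium_template):
        dataset = self._symmetric_dataset(cranium_template, 6, 0.02, seed=11)
        _, sym = gpa_with_object_symmetry(dataset)
        assert np.abs(sym.asymmetric).max() < 1e-9

    def test_decomposition_reconstructs_aligned_shapes(self, cranium_template):
        dataset = self._symmetric_dataset(cranium_template, 6, 0.02, seed=12,
                                          asym=0.01)
        result, sym = gpa_with_object_symmetry(dataset)
        np.testing.assert_allclose(
            sym.symmetric + sym.asymmetric, result.aligned, atol=1e-12)

    def test_decomposition_orthogonality(self, cranium_template):
        # total SS of the 2n configurations = symmetric SS + asymmetric SS
        dataset = self._symmetric_dataset(cranium_template, 8, 0.02, seed=13,
                                          asym=0.01)
        result, sym = gpa_with_object_symmetry(dataset)
        consensus = sym.consensus
        sym_ss = ((sym.symmetric - consensus[None]) ** 2).sum()
        asym_ss = (sym.asymmetric**2).sum()
        # each specimen contributes both copies: ||s+d-c||^2 + ||s-d-c||^2
        total = 2 * sym_ss + 2 * asym_ss
        assert total == pytest.approx(float(result.ss_trace[-1]), rel=1e-8)

    def test_consensus_is_symmetric(self, cranium_template):
        dataset = self._symmetric_dataset(cranium_template, 6, 0.02, seed=14,
                                          asym=0.02)
        _, sym = gpa_with_object_symmetry(dataset)
        mirrored = reflect_relabel(sym.consensus, cranium_template)
        assert procrustes_distance(sym.consensus, mirrored) < 1e-8

    def test_mirror_twin_has_identical_symmetric_component(self, cranium_template):
        rng = np.random.default_rng(15)
        base = make_symmetric_mean(cranium_template, seed=20)
        shape = base + 0.03 * rng.normal(size=base.shape)
        twin = reflect_relabel(shape, cranium_template)
        dataset = make_dataset(cranium_template, np.stack([shape, twin]))
        _, sym = gpa_with_object_symmetry(dataset)
        assert procrustes_distance(sym.symmetric[0], sym.symmetric[1]) < 1e-9

    def test_symmetric_component_rank_matches_projection_oracle(
            self, cranium_template):
        # independent oracle: dimension of the symmetric tangent subspace by
        # brute-force projection of random tangent vectors
        template = cranium_template
        rng = np.random.default_rng(16)
        k = template.n_landmarks
        samples = []
        for _ in range(200):
            v = rng.normal(size=(k, 3))
            sym_v = symmetrize(v, template)
            sym_v -= sym_v.mean(axis=0)  # remove symmetric translations
            samples.append(sym_v.ravel())
        oracle_rank = np.linalg.matrix_rank(np.array(samples), tol=1e-8)
        # the 4 remaining Procrustes constraints: scale (1), in-plane
        # translations were removed above (2 of 3: x-translation is not
        # symmetric), rotation about the symmetry axis (1)
        expected_sym_dim = oracle_rank - 2  # minus scale, in-plane rotation
        dataset = self._symmetric_dataset(template, 300, 0.002, seed=17)
        _, sym = gpa_with_object_symmetry(dataset)
        flat = sym.flattened()
        centred = flat - flat.mean(axis=0)
        svals = np.linalg.svd(centred, compute_uv=False)
        # in-subspace singular values sit well above the curvature
        # (sphere-constraint) residuals; 5% of the leading value separates them
        n_nonzero = int((svals > 0.05 * svals[0]).sum())
        assert n_nonzero == expected_sym_dim
        from morphotraj.allometry import shape_space_dimension
        assert expected_sym_dim == shape_space_dimension(
            301, k, symmetric=True, n_paired=len(template.pairs),
            n_midline=len(template.midline))

    def test_template_without_symmetry_rejected(self, mandible_template):
        rng = np.random.default_rng(18)
        dataset = make_dataset(mandible_template, rng.normal(size=(3, 9, 3)))
        with pytest.raises(ValueError, match="symmetry"):
            gpa_with_object_symmetry(dataset)


class TestProcrustesDistance:
    def test_identity_and_symmetry(self):
        rng = np.random.default_rng(19)
        a, b = rng.normal(size=(2, 10, 3))
        assert procrustes_distance(a, a) == pytest.approx(0.0, abs=1e-12)
        assert procrustes_distance(a, b) == pytest.approx(
            procrustes_distance(b, a), abs=1e-10)

    def test_equals_align_residual(self):
        rng = np.random.default_rng(20)
        a, b = rng.normal(size=(2, 10, 3))
        _, residual = align_to(a, b)
        assert procrustes_distance(a, b) == pytest.approx(np.sqrt(residual))

    @pytest.mark.parametrize("seed", [21, 22])
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 3, 3))
        assert procrustes_distance(a, b) == pytest.approx(
            brute_force_procrustes_distance(a, b), abs=1e-4)
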