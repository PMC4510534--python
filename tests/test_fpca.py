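"""Coefficient fitting, eigen-decomposition, scores and reconstruction."""

import numpy as np
import pytest

from imgfpc import (
    CoefficientMatrix,
    FourierBasis,
    ImageSignal,
    center_coefficients,
    compute_scores,
    eigen_decompose,
    eval_eigenfunction,
    fit_coefficients,
    reconstruct,
)
from imgfpc.errors import (
    CohortInconsistencyError,
    ContractViolationError,
    DegenerateCohortError,
    IdentifiabilityError,
    InvalidArgumentError,
)
from imgfpc.signals import pixel_grid

from conftest import random_images


def _grid_image(fn, H, W):
    s, t = pixel_grid(H), pixel_grid(W)
    return ImageSignal(values=fn(s[:, None], t[None, :]))


class TestFitCoefficients:
    def test_constant_image_loads_only_the_constant_term(self):
        images = [ImageSignal(values=np.full((16, 16), 5.0))] * 2
        coef = fit_coefficients(images, FourierBasis(4))
        expected = np.zeros(16)
        expected[0] = 5.0
        assert np.abs(coef.C[0] - expected).max() < 1e-8

    def test_pure_tensor_function_recovers_unit_coefficient(self):
        basis = FourierBasis(4)
        # x(s,t) = phi_2(s) phi_3(t): coefficient slot (1,2) -> 1*4+2 = 6
        img = _grid_image(
            lambda s, t: (np.sqrt(2) * np.sin(2 * np.pi * s))
            * (np.sqrt(2) * np.cos(2 * np.pi * t)),
            64, 64,
        )
        coef = fit_coefficients([img, img], basis)
        target = np.zeros(16)
        target[6] = 1.0
        assert np.abs(coef.C[0] - target).max() < 1e-3

    def test_residual_nonincreasing_in_basis_size(self, rng):
        """Nested least squares: richer basis never fits worse."""
        # smooth random image from a K=10 expansion plus small noise
        b10 = FourierBasis(10)
        s, t = pixel_grid(48), pixel_grid(48)
        coeff = rng.standard_normal((10, 10)) * 0.3
        img = ImageSignal(values=b10(s) @ coeff @ b10(t).T + 0.01 * rng.standard_normal((48, 48)))
        res = {}
        for K in (4, 8):
            basis = FourierBasis(K)
            c = fit_coefficients([img, img], basis)
            fitted = basis(s) @ c.C[0].reshape(K, K) @ basis(t).T
            res[K] = np.linalg.norm(img.values - fitted)
        assert res[8] <= res[4] + 1e-12

    def test_mixed_shapes_rejected(self, rng):
        images = [
            ImageSignal(values=rng.standard_normal((16, 16))),
            ImageSignal(values=rng.standard_normal((8, 8))),
        ]
        with pytest.raises(CohortInconsistencyError):
            fit_coefficients(images, FourierBasis(3))

    def test_overparameterized_basis_rejected(self, rng):
        with pytest.raises(IdentifiabilityError):
            fit_coefficients(random_images(rng, 2, 4, 4), FourierBasis(5))


class TestCentering:
    def test_identical_rows_center_to_zero(self):
        C = CoefficientMatrix(C=np.ones((2, 4)), K=2)
        assert np.abs(center_coefficients(C).C).max() == 0.0

    def test_mean_subtraction(self):
        C = CoefficientMatrix(C=np.array([[1.0], [3.0]]), K=1)
        out = center_coefficients(C)
        assert np.allclose(out.C, [[-1.0], [1.0]])
        assert np.allclose(out.column_mean, [2.0])

    def test_column_sums_vanish(self, rng):
        C = CoefficientMatrix(C=rng.standard_normal((7, 9)), K=3)
        out = center_coefficients(C)
        assert np.abs(out.C.sum(axis=0)).max() < 1e-10
        assert out.centered

    def test_single_row_rejected(self):
        with pytest.raises(DegenerateCohortError):
            center_coefficients(CoefficientMatrix(C=np.ones((1, 4)), K=2))


class TestEigenDecompose:
    def test_two_point_cohort(self):
        C = CoefficientMatrix(
            C=np.array([[1.0, 0.0, 0.0, 0.0], [-1.0, 0.0, 0.0, 0.0]]),
            K=2, centered=True,
        )
        es = eigen_decompose(C, J=2)
        assert es.eigenvalues[0] == pytest.approx(1.0)
        assert es.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(np.abs(es.coeff_vectors[:, 0]), [1, 0, 0, 0])
        assert es.coeff_vectors[0, 0] > 0  # sign convention

    def test_matches_dense_eigensolver_oracle(self, rng):
        C = center_coefficients(
            CoefficientMatrix(C=rng.standard_normal((10, 9)), K=3)
        )
        es = eigen_decompose(C, J=9)
        S = C.C.T @ C.C / 10
        ref_vals, ref_vecs = np.linalg.eigh(S)
        ref_vals = ref_vals[::-1]
        assert np.abs(es.eigenvalues - np.clip(ref_vals, 0, None)).max() < 1e-8
        for j in range(9):
            v = ref_vecs[:, ::-1][:, j]
            dot = abs(v @ es.coeff_vectors[:, j])
            assert dot == pytest.approx(1.0, abs=1e-6)

    def test_rank_bound_on_nonzero_eigenvalues(self, rng):
        N, K = 4, 3  # N - 1 < K^2
        C = center_coefficients(
            CoefficientMatrix(C=rng.standard_normal((N, K * K)), K=K)
        )
        es = eigen_decompose(C, J=K * K)
        assert np.sum(es.eigenvalues > 1e-10) <= N - 1

    def test_requires_centered_input(self, rng):
        C = CoefficientMatrix(C=rng.standard_normal((5, 4)), K=2)
        with pytest.raises(ContractViolationError):
            eigen_decompose(C, J=2)

    def test_J_out_of_range_rejected(self, rng):
        C = center_coefficients(CoefficientMatrix(C=rng.standard_normal((5, 4)), K=2))
        with pytest.raises(InvalidArgumentError):
            eigen_decompose(C, J=5)


class TestEigenfunctions:
    def test_unit_vector_gives_constant_function(self, centered_coef):
        coef, basis = centered_coef
        es = eigen_decompose(coef, J=3)
        # fabricate a system whose first vector is e_1
        from imgfpc.fpca import EigenSystem

        B = np.zeros((25, 1))
        B[0, 0] = 1.0
        es1 = EigenSystem(eigenvalues=np.array([1.0]), coeff_vectors=B,
                          total_variance=1.0, K=5)
        pts = np.column_stack([np.linspace(0, 1, 9), np.linspace(0, 1, 9)])
        vals = eval_eigenfunction(es1, basis, 0, pts)
        assert np.allclose(vals, 1.0)

    def test_linearity_closed_form(self, centered_coef):
        _, basis = centered_coef
        from imgfpc.fpca import EigenSystem

        B = np.zeros((25, 1))
        B[1, 0] = B[2, 0] = 1 / np.sqrt(2)  # (e_2 + e_3)/sqrt(2)
        es = EigenSystem(eigenvalues=np.array([1.0]), coeff_vectors=B,
                         total_variance=1.0, K=5)
        val = eval_eigenfunction(es, basis, 0, [(0.25, 0.25)])[0]
        phi = basis(np.array([0.25]))[0]
        expected = (phi[0] * phi[1] + phi[0] * phi[2]) / np.sqrt(2)
        assert val == pytest.approx(expected)

    def test_quadrature_orthonormality(self, centered_coef):
        """Integral of beta_j beta_m over the square ~ delta_jm."""
        coef, basis = centered_coef
        es = eigen_decompose(coef, J=4)
        g = pixel_grid(256)
        S, T = np.meshgrid(g, g, indexing="ij")
        pts = np.column_stack([S.ravel(), T.ravel()])
        B = np.column_stack(
            [eval_eigenfunction(es, basis, j, pts) for j in range(4)]
        )
        gram = B.T @ B / (256 * 256)
        assert np.abs(gram - np.eye(4)).max() < 1e-4

    def test_index_out_of_range(self, centered_coef):
        coef, basis = centered_coef
        es = eigen_decompose(coef, J=2)
        with pytest.raises(InvalidArgumentError):
            eval_eigenfunction(es, basis, 2, [(0.5, 0.5)])


class TestScores:
    def test_row_equal_to_eigenvector_scores_unit(self, rng):
        C0 = center_coefficients(
            CoefficientMatrix(C=rng.standard_normal((8, 9)), K=3)
        )
        es = eigen_decompose(C0, J=4)
        # replace first row by b_1 (no re-centering: direct identity check)
        C1 = CoefficientMatrix(
            C=np.vstack([es.coeff_vectors[:, 0], C0.C[1:]]),
            K=3, centered=True, column_mean=C0.column_mean,
        )
        sm = compute_scores(C1, es)
        assert sm.xi[0, 0] == pytest.approx(1.0)
        assert np.abs(sm.xi[0, 1:]).max() < 1e-8

    def test_scores_match_quadrature_of_product_integral(self, small_cohort):
        """xi_ij = integral x_i beta_j, checked by midpoint quadrature."""
        images, _ = small_cohort
        basis = FourierBasis(5)
        coef = center_coefficients(fit_coefficients(images, basis))
        es = eigen_decompose(coef, J=3)
        sm = compute_scores(coef, es)
        n = 256
        g = pixel_grid(n)
        S, T = np.meshgrid(g, g, indexing="ij")
        pts = np.column_stack([S.ravel(), T.ravel()])
        Bg = basis(g)
        for i in (0, 7):
            xi_c = (coef.C[i]).reshape(5, 5)
            x_grid = Bg @ xi_c @ Bg.T  # centered smoothed image on fine grid
            for j in range(3):
                beta = eval_eigenfunction(es, basis, j, pts).reshape(n, n)
                quad = (x_grid * beta).sum() / (n * n)
                assert quad == pytest.approx(sm.xi[i, j], abs=1e-3)

    def test_score_variance_equals_eigenvalue(self, centered_coef):
        coef, _ = centered_coef
        es = eigen_decompose(coef, J=5)
        sm = compute_scores(coef, es)
        assert np.abs(sm.xi.var(axis=0) - es.eigenvalues).max() < 1e-8

    def test_variance_explained_fractions(self, centered_coef):
        coef, _ = centered_coef
        es = eigen_decompose(coef, J=6)
        sm = compute_scores(coef, es)
        ve = sm.variance_explained
        assert np.all(ve >= 0) and np.all(ve <= 1)
        assert np.all(np.diff(ve) <= 1e-12)
        assert ve.sum() <= 1 + 1e-8

    def test_dimension_mismatch_rejected(self, rng, centered_coef):
        _, _ = centered_coef
        coef_a = center_coefficients(CoefficientMatrix(C=rng.standard_normal((6, 9)), K=3))
        coef_b = center_coefficients(CoefficientMatrix(C=rng.standard_normal((6, 4)), K=2))
        es = eigen_decompose(coef_a, J=2)
        with pytest.raises(ContractViolationError):
            compute_scores(coef_b, es)


class TestReconstruct:
    def _setup(self, cohort, J=None):
        images, _ = cohort
        basis = FourierBasis(5)
        coef = center_coefficients(fit_coefficients(images, basis))
        es = eigen_decompose(coef, J=J or 25)
        sm = compute_scores(coef, es)
        return images, basis, coef, es, sm

    def test_full_rank_reconstruction_equals_smoothed_image(self, small_cohort):
        images, basis, coef, es, sm = self._setup(small_cohort)
        H, W = images[0].shape
        rec = reconstruct(sm, es, basis, coef, 3, es.n_components, H, W)
        Bs, Bt = basis(pixel_grid(H)), basis(pixel_grid(W))
        smoothed = Bs @ (coef.C[3] + coef.column_mean).reshape(5, 5) @ Bt.T
        assert np.abs(rec.values - smoothed).max() < 1e-8

    def test_zero_components_returns_cohort_mean(self, small_cohort):
        images, basis, coef, es, sm = self._setup(small_cohort)
        H, W = images[0].shape
        rec = reconstruct(sm, es, basis, coef, 0, 0, H, W)
        Bs, Bt = basis(pixel_grid(H)), basis(pixel_grid(W))
        mean_img = Bs @ coef.column_mean.reshape(5, 5) @ Bt.T
        assert np.abs(rec.values - mean_img).max() < 1e-10

    def test_error_nonincreasing_in_components(self, small_cohort):
        images, basis, coef, es, sm = self._setup(small_cohort)
        H, W = images[0].shape
        errors = []
        for J_use in (2, 5, 10, es.n_components):
            rec = reconstruct(sm, es, basis, coef, 1, J_use, H, W)
            errors.append(np.sum((rec.values - images[1].values) ** 2))
        assert all(a >= b - 1e-10 for a, b in zip(errors, errors[1:]))

    def test_bad_index_rejected(self, small_cohort):
        images, basis, coef, es, sm = self._setup(small_cohort)
        with pytest.raises(InvalidArgumentError):
            reconstruct(sm, es, basis, coef, 99, 2, 24, 24)


def test_variance_conservation(centered_coef):
    """Sum of all eigenvalues equals total coefficient variance."""
    coef, _ = centered_coef
    es = eigen_decompose(coef, J=25)
    assert es.eigenvalues.sum() == pytest.approx(es.total_variance, abs=1e-8)
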