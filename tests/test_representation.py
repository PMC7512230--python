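"""Curve representation: Gram matrix, ridge fit, eigen-truncation."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from mesfda import (
    KernelCurveRepresenter,
    KernelSpec,
    SampledCurveSet,
    eigendecompose,
    fit_ridge_coefficients,
    gaussian_gram,
    project_coefficients,
    reconstruct_curve,
    represent_sample,
    select_kernel_params_cv,
)
from mesfda.representation import _fit_ridge_matrix


class TestGaussianGram:
    def test_unit_diagonal_and_symmetry(self, rng):
        grid = np.sort(rng.uniform(0, 1, 17))
        k = gaussian_gram(grid, sigma=3.7)
        assert np.allclose(np.diag(k), 1.0)
        assert np.allclose(k, k.T)

    def test_two_point_off_diagonal(self):
        k = gaussian_gram([0.0, 1.0], sigma=10.0)
        assert np.allclose(k, [[1.0, np.exp(-10)], [np.exp(-10), 1.0]])

    def test_three_point_hand_evaluation(self):
        k = gaussian_gram([0.0, 0.5, 1.0], sigma=1.0)
        e25, e1 = np.exp(-0.25), np.exp(-1.0)
        expected = np.array([[1, e25, e1], [e25, 1, e25], [e1, e25, 1]])
        assert np.allclose(k, expected)

    @pytest.mark.parametrize("bad_sigma", [0.0, -1.0])
    def test_nonpositive_sigma_rejected(self, bad_sigma):
        with pytest.raises(ValueError, match="sigma"):
            gaussian_gram([0.0, 1.0], bad_sigma)

    def test_duplicate_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            gaussian_gram([0.0, 0.5, 0.5, 1.0], 1.0)


class TestRidgeFit:
    def test_zero_curve_gives_zero_coefficients(self):
        k = gaussian_gram(np.linspace(0, 1, 8), 5.0)
        a = fit_ridge_coefficients(np.zeros(8), k, gamma=0.1)
        assert np.allclose(a, 0.0)

    def test_hand_solved_identity_gram(self):
        # (0.5*2*I + I) a = y  =>  2I a = y
        a = fit_ridge_coefficients(np.array([2.0, 4.0]), np.eye(2), gamma=0.5)
        assert np.allclose(a, [1.0, 2.0])

    def test_interpolation_limit(self, rng):
        grid = np.linspace(0, 1, 10)
        k = gaussian_gram(grid, 8.0)
        y = np.sin(2 * np.pi * grid)
        a = fit_ridge_coefficients(y, k, gamma=1e-10)
        assert np.allclose(k @ a, y, atol=1e-6)

    def test_linear_system_residual_invariant(self, rng):
        grid = np.linspace(0, 1, 30)
        k = gaussian_gram(grid, 10.0)
        y = rng.standard_normal((5, 30))
        a = _fit_ridge_matrix(y, k, gamma=0.15)
        system = 0.15 * 30 * np.eye(30) + k
        for row_a, row_y in zip(a, y):
            resid = np.linalg.norm(system @ row_a - row_y)
            assert resid <= 1e-8 * np.linalg.norm(row_y)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            fit_ridge_coefficients(np.zeros(3), np.eye(2), 0.1)


class TestEigendecompose:
    def test_identity_spectrum(self):
        fact = eigendecompose(np.eye(4))
        assert np.allclose(fact.eigenvalues, 1.0)
        assert fact.numerical_rank == 4
        assert np.allclose(fact.eigenvectors, np.eye(4))

    def test_rank_one_matrix(self, rng):
        u = rng.standard_normal(6)
        fact = eigendecompose(np.outer(u, u))
        assert fact.numerical_rank == 1
        assert np.isclose(fact.eigenvalues[0], u @ u)

    def test_characteristic_polynomial_oracle(self):
        """Eigenvalues of the 3x3 worked Gram match brute-force root finding."""
        k = gaussian_gram([0.0, 0.5, 1.0], sigma=1.0)
        # det(K - x I) expanded by the first row, with Polynomial arithmetic
        P = np.polynomial.Polynomial
        entry = [[P([k[i, j]]) - P([0, 1]) * float(i == j) for j in range(3)]
                 for i in range(3)]
        det = (entry[0][0] * (entry[1][1] * entry[2][2] - entry[1][2] * entry[2][1])
               - entry[0][1] * (entry[1][0] * entry[2][2] - entry[1][2] * entry[2][0])
               + entry[0][2] * (entry[1][0] * entry[2][1] - entry[1][1] * entry[2][0]))
        roots = np.sort(det.roots().real)[::-1]
        assert np.allclose(np.sort(eigendecompose(k).eigenvalues)[::-1], roots, atol=1e-10)

    def test_reconstruction_and_orthonormality(self, rng):
        k = gaussian_gram(np.sort(rng.uniform(0, 1, 12)), 4.0)
        fact = eigendecompose(k)
        v, lam = fact.eigenvectors, fact.eigenvalues
        assert np.allclose(v.T @ v, np.eye(12), atol=1e-10)
        assert np.allclose(v @ np.diag(lam) @ v.T, k, atol=1e-10)
        assert np.all(np.diff(lam) <= 1e-12)

    def test_sign_convention(self, rng):
        fact = eigendecompose(gaussian_gram(np.linspace(0, 1, 9), 6.0))
        for col in fact.eigenvectors.T:
            assert col[np.argmax(np.abs(col))] > 0

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestProjection:
    def test_zero_coefficients(self):
        fact = eigendecompose(gaussian_gram(np.linspace(0, 1, 5), 2.0))
        assert np.allclose(project_coefficients(np.zeros(5), fact, 3), 0.0)

    def test_identity_gram_passthrough(self, rng):
        fact = eigendecompose(np.eye(5))
        a = rng.standard_normal(5)
        assert np.allclose(project_coefficients(a, fact, 3), a[:3])

    def test_explicit_summation_oracle(self, rng):
        fact = eigendecompose(gaussian_gram([0.0, 0.5, 1.0], 1.0))
        a = rng.standard_normal(3)
        z = project_coefficients(a, fact, 3)
        for j in range(3):
            expected = fact.eigenvalues[j] * sum(
                a[i] * fact.eigenvectors[i, j] for i in range(3))
            assert np.isclose(z[j], expected)

    def test_truncation_beyond_rank_rejected(self, rng):
        u = rng.standard_normal(4)
        fact = eigendecompose(np.outer(u, u))
        with pytest.raises(ValueError, match="rank"):
            project_coefficients(np.ones(4), fact, 2)

    def test_sqrt_lambda_switch(self, rng):
        fact = eigendecompose(gaussian_gram(np.linspace(0, 1, 6), 3.0))
        a = rng.standard_normal(6)
        z_lam = project_coefficients(a, fact, 4, scaling="lambda")
        z_sqrt = project_coefficients(a, fact, 4, scaling="sqrt_lambda")
        assert np.allclose(z_lam, z_sqrt * np.sqrt(fact.eigenvalues[:4]))


class TestRepresentSample:
    def test_single_zero_curve(self):
        curves = SampledCurveSet(np.linspace(0, 1, 10), np.zeros((1, 10)))
        coeffs = represent_sample(curves, KernelSpec(10, 0.15))
        assert coeffs.coefficients.shape[0] == 1
        assert np.allclose(coeffs.coefficients, 0.0)

    def test_identical_curves_identical_rows(self, rng):
        grid = np.linspace(0, 1, 20)
        y = np.sin(3 * grid)
        curves = SampledCurveSet(grid, np.vstack([y, y]))
        coeffs = represent_sample(curves, KernelSpec(10, 0.15))
        assert np.array_equal(coeffs.coefficients[0], coeffs.coefficients[1])

    def test_pipeline_equals_composition(self, scenario_a_sample, reference_kernel):
        coeffs = represent_sample(scenario_a_sample, reference_kernel,
                                  truncation_rule="ev:0.999")
        gram = gaussian_gram(scenario_a_sample.grid, reference_kernel.sigma)
        fact = eigendecompose(gram)
        for l in [0, 17, 399]:
            a = fit_ridge_coefficients(scenario_a_sample.values[l], gram,
                                       reference_kernel.gamma)
            z = project_coefficients(a, fact, coeffs.d)
            assert np.allclose(coeffs.coefficients[l], z, atol=1e-10)

    def test_bit_reproducible(self, scenario_a_sample, reference_kernel):
        c1 = represent_sample(scenario_a_sample, reference_kernel)
        c2 = represent_sample(scenario_a_sample, reference_kernel)
        assert np.array_equal(c1.coefficients, c2.coefficients)

    def test_truncation_monotonicity(self, rng):
        """Grid-evaluated truncation error is non-increasing in d and ~0 at full rank."""
        grid = np.linspace(0, 1, 25)
        y = np.sin(2 * np.pi * grid) + 0.1 * rng.standard_normal(25)
        gram = gaussian_gram(grid, 10.0)
        fact = eigendecompose(gram)
        a = fit_ridge_coefficients(y, gram, 0.15)
        fitted = gram @ a
        errors = []
        for d in range(1, fact.numerical_rank + 1):
            v_d = fact.eigenvectors[:, :d]
            z = project_coefficients(a, fact, d)
            errors.append(np.linalg.norm(fitted - v_d @ z))
        assert all(e2 <= e1 + 1e-10 for e1, e2 in zip(errors, errors[1:]))
        assert errors[-1] <= 1e-6 * max(1.0, np.linalg.norm(fitted))


class TestReconstruct:
    def test_zero_coefficients_zero_curve(self):
        grid = np.linspace(0, 1, 7)
        assert np.allclose(reconstruct_curve(np.zeros(7), grid, grid, 5.0), 0.0)

    def test_training_points_equal_gram_product(self, rng):
        grid = np.linspace(0, 1, 9)
        a = rng.standard_normal(9)
        gram = gaussian_gram(grid, 4.0)
        assert np.allclose(reconstruct_curve(a, grid, grid, 4.0), gram @ a)

    def test_interpolation_limit(self):
        grid = np.linspace(0, 1, 12)
        y = np.cos(3 * grid)
        gram = gaussian_gram(grid, 10.0)
        a = fit_ridge_coefficients(y, gram, 1e-10)
        assert np.allclose(reconstruct_curve(a, grid, grid, 10.0), y, atol=1e-5)


class TestCrossValidation:
    def _smooth_sample(self):
        grid = np.linspace(0, 1, 40)
        values = np.vstack([np.sin(2 * np.pi * grid), np.cos(2 * np.pi * grid)])
        return SampledCurveSet(grid, values)

    def test_single_candidate_returned(self):
        spec = select_kernel_params_cv(self._smooth_sample(), [3.0], [0.2], seed=0)
        assert (spec.sigma, spec.gamma) == (3.0, 0.2)

    def test_small_gamma_wins_on_noiseless_curve(self):
        spec = select_kernel_params_cv(self._smooth_sample(), [10.0], [1e-4, 1e2], seed=0)
        assert spec.gamma == 1e-4

    def test_seed_determinism(self):
        sample = self._smooth_sample()
        grids = ([1.0, 5.0, 10.0], [0.01, 0.1, 1.0])
        s1 = select_kernel_params_cv(sample, *grids, seed=42)
        s2 = select_kernel_params_cv(sample, *grids, seed=42)
        assert (s1.sigma, s1.gamma) == (s2.sigma, s2.gamma)

    def test_degenerate_folds_rejected(self):
        sample = self._smooth_sample()
        with pytest.raises(ValueError):
            select_kernel_params_cv(sample, [1.0], [0.1], n_folds=100, seed=0)


class TestKernelCurveRepresenter:
    def test_matches_functional_pipeline(self, scenario_a_sample, reference_kernel):
        rep = KernelCurveRepresenter(sigma=10.0, gamma=0.15)
        z = rep.fit_transform(scenario_a_sample.values, grid=scenario_a_sample.grid)
        coeffs = represent_sample(scenario_a_sample, reference_kernel)
        assert rep.d_ == coeffs.d
        assert np.allclose(z, coeffs.coefficients, atol=1e-12)

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        rep = KernelCurveRepresenter(sigma=5.0, gamma=0.05, truncation=3)
        cloned = clone(rep)
        assert cloned.get_params() == rep.get_params()

    def test_fixed_truncation(self, scenario_a_sample):
        rep = KernelCurveRepresenter(truncation=4).fit(scenario_a_sample.values,
                                                       grid=scenario_a_sample.grid)
        z = rep.transform(scenario_a_sample.values)
        assert z.shape == (400, 4)


def test_ordering_robust_to_kernel_parameters(scenario_a_sample):
    """Center-outward ordering is stable across (sigma, gamma) settings.

    Orderings are compared at a common truncation order (the smaller of the
    two eigenvalue-rule orders) so that the two representations describe the
    same number of coordinates.
    """
    from mesfda import fit_parametric_mes, classify_parametric

    settings = [(10.0, 0.15), (5.0, 0.05)]
    coeff_sets = {sg: represent_sample(scenario_a_sample, KernelSpec(*sg))
                  for sg in settings}
    d_common = min(c.d for c in coeff_sets.values())
    scores = {}
    for sg in settings:
        coeffs = represent_sample(scenario_a_sample, KernelSpec(*sg),
                                  truncation_rule=d_common)
        mes = fit_parametric_mes(coeffs.coefficients, nu=0.10,
                                 threshold_mode="empirical", seed=0)
        scores[sg] = classify_parametric(mes, coeffs.coefficients).scores
    rho = spearmanr(scores[settings[0]], scores[settings[1]]).statistic
    assert rho > 0.9
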