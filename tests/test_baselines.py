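"""PCA/EFA arm: correlations, loadings, rotations, retention diagnostics,
fit indices."""

import numpy as np
import pytest

from opnmfkit import (
    assign_items_from_loadings,
    correlation_matrix,
    efa_fit,
    generate_null,
    generate_scores,
    parallel_analysis,
    pca_loadings,
    promax_rotate,
    scree_eigenvalues,
    tucker_lewis_index,
)
from opnmfkit.baselines import max_identifiable_factors, varimax


class TestCorrelationMatrix:
    def test_duplicated_items_correlate_perfectly(self, rng):
        base = rng.random(50)
        X = np.vstack([base, base, rng.random(50)])
        R = correlation_matrix(X)
        assert R[0, 1] == pytest.approx(1.0)

    def test_zero_variance_item_named_in_error(self):
        X = np.vstack([np.full(10, 2.0), np.random.default_rng(0).random(10)])
        with pytest.raises(ValueError, match="0"):
            correlation_matrix(X)

    def test_positive_semidefinite_with_unit_diagonal(self):
        sm = generate_null(p=17, n=334, seed=3)
        R = correlation_matrix(sm)
        assert np.linalg.eigvalsh(R).min() >= -1e-10
        np.testing.assert_allclose(np.diag(R), 1.0)
        off = R[~np.eye(17, dtype=bool)]
        assert np.all(np.abs(off) < 4 / np.sqrt(334))


class TestPcaLoadings:
    def test_identity_correlation_gives_unit_eigenvalues(self):
        L = pca_loadings(np.eye(5), 5)
        np.testing.assert_allclose(L.eigenvalues, 1.0)
        np.testing.assert_allclose(np.abs(L.loadings) @ np.abs(L.loadings.T), np.eye(5),
                                   atol=1e-10)

    def test_two_by_two_closed_form(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        L = pca_loadings(R, 1)
        np.testing.assert_allclose(L.loadings[:, 0], np.sqrt(1.5 / 2), atol=1e-12)

    def test_full_rank_reconstructs_correlation(self, rng):
        sm, _ = generate_scores(p=8, k=2, n=100, noise_sd=0.3, seed=5)
        R = correlation_matrix(sm)
        L = pca_loadings(R, 8)
        np.testing.assert_allclose(L.loadings @ L.loadings.T, R, atol=1e-8)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            pca_loadings(np.eye(4), 5)


class TestEfaFit:
    lam = np.array([0.8, 0.7, 0.6, 0.5, 0.4])

    def _one_factor_R(self):
        return np.outer(self.lam, self.lam) + np.diag(1 - self.lam**2)

    @pytest.mark.parametrize("method", ["minres", "ml"])
    def test_recovers_analytic_one_factor_structure(self, method):
        fit = efa_fit(self._one_factor_R(), 1, n_subjects=334, method=method)
        np.testing.assert_allclose(np.abs(fit.loadings[:, 0]), self.lam, atol=1e-3)
        np.testing.assert_allclose(fit.communalities, self.lam**2, atol=2e-3)

    def test_population_input_gives_near_zero_model_chi_square(self):
        fit = efa_fit(self._one_factor_R(), 1, n_subjects=334)
        assert fit.fit_stats["chi_model"] == pytest.approx(0.0, abs=1e-4)
        assert fit.fit_stats["tli"] > 0.999

    def test_identifiability_bound_enforced(self):
        with pytest.raises(ValueError):
            efa_fit(self._one_factor_R(), 3, n_subjects=334)  # p=5 allows k<=2
        assert max_identifiable_factors(17) == 11

    def test_minres_solution_is_locally_optimal(self, rng):
        R = self._one_factor_R()
        fit = efa_fit(R, 1, n_subjects=334)
        psi = fit.uniquenesses

        def obj(p):
            from opnmfkit.baselines import _conditional_loadings_minres

            L = _conditional_loadings_minres(R, p, 1)
            resid = R - L @ L.T
            np.fill_diagonal(resid, 0.0)
            return np.sum(resid**2)

        base = obj(psi)
        for _ in range(10):
            delta = rng.normal(scale=1e-3, size=psi.shape)
            assert obj(np.clip(psi + delta, 1e-4, 1.0)) >= base - 1e-10


class TestPromax:
    def test_k1_is_identity(self, rng):
        L = rng.random((6, 1))
        out = promax_rotate(L)
        np.testing.assert_array_equal(out.loadings, L)
        np.testing.assert_array_equal(out.factor_correlations, [[1.0]])

    def test_orthogonal_simple_structure_keeps_phi_near_identity(self):
        L = np.zeros((8, 2))
        L[:4, 0] = 0.8
        L[4:, 1] = 0.8
        out = promax_rotate(L)
        off = out.factor_correlations[0, 1]
        assert abs(off) <= 0.02

    def test_rotation_matrix_consistency_without_kaiser(self, rng):
        L = rng.normal(size=(17, 3)) * 0.5
        out = promax_rotate(L, kaiser=False)
        np.testing.assert_allclose(out.loadings, L @ out.rotation_matrix, atol=1e-10)
        # Phi is the normalized inverse cross-product of the oblique part
        phi = out.factor_correlations
        np.testing.assert_allclose(np.diag(phi), 1.0, atol=1e-10)
        assert np.linalg.eigvalsh(phi).min() >= -1e-8

    def test_varimax_preserves_column_span(self, rng):
        L = rng.normal(size=(10, 3))
        V, T = varimax(L, normalize=False)
        np.testing.assert_allclose(V, L @ T, atol=1e-10)
        np.testing.assert_allclose(T.T @ T, np.eye(3), atol=1e-10)


class TestParallelAnalysis:
    def test_thresholds_decrease_with_position(self):
        sm = generate_null(p=17, n=334, seed=1)
        pa = parallel_analysis(sm, n_sim=50, seed=2)
        assert np.all(np.diff(pa.pa_thresholds) <= 1e-12)

    def test_strong_two_factor_data_retains_two(self):
        hits = 0
        for s in range(10):
            sm, _ = generate_scores(p=17, k=2, n=334, noise_sd=0.3, seed=s)
            pa = parallel_analysis(sm, n_sim=100, seed=100 + s)
            hits += pa.k_parallel == 2
        assert hits >= 9

    def test_seed_determinism(self):
        sm = generate_null(p=10, n=100, seed=0)
        a = parallel_analysis(sm, n_sim=30, seed=5)
        b = parallel_analysis(sm, n_sim=30, seed=5)
        np.testing.assert_array_equal(a.pa_thresholds, b.pa_thresholds)
        assert a.k_parallel == b.k_parallel

    def test_efa_basis_uses_reduced_correlation(self):
        sm, _ = generate_scores(p=17, k=2, n=334, noise_sd=0.3, seed=9)
        pa = parallel_analysis(sm, n_sim=50, basis="efa-eigen", seed=1)
        # reduced-correlation eigenvalues sum to less than p
        assert pa.eigenvalues.sum() < 17


class TestScree:
    def test_identity_is_flat_with_no_elbow(self):
        diag = scree_eigenvalues(np.eye(6))
        np.testing.assert_allclose(diag.eigenvalues, 1.0)
        assert diag.k_scree is None

    def test_rank_two_spectrum_has_elbow_at_two(self):
        sm, _ = generate_scores(p=17, k=2, n=2000, noise_sd=0.2, seed=12)
        diag = scree_eigenvalues(correlation_matrix(sm))
        assert diag.k_scree == 2

    def test_eigenvalue_sum_equals_item_count(self):
        sm, _ = generate_scores(p=17, k=3, n=100, noise_sd=0.4, seed=2)
        diag = scree_eigenvalues(correlation_matrix(sm))
        assert diag.eigenvalues.sum() == pytest.approx(17.0, abs=1e-8)


class TestTuckerLewis:
    def test_perfect_model_gives_one(self):
        assert tucker_lewis_index(100, 100, 1000, 100) == pytest.approx(1.0)

    def test_no_improvement_over_null_gives_zero(self):
        assert tucker_lewis_index(500, 50, 1000, 100) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        null_ratio = 1000 / 136
        expected = (null_ratio - 120 / 100) / (null_ratio - 1)
        assert tucker_lewis_index(120, 100, 1000, 136) == pytest.approx(expected, abs=1e-12)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            tucker_lewis_index(10, 0, 100, 10)


class TestAssignFromLoadings:
    def test_diagonal_dominant_blocks(self):
        L = np.array([[0.8, 0.1], [0.7, 0.2], [0.1, 0.9], [0.2, 0.6]])
        np.testing.assert_array_equal(assign_items_from_loadings(L), [0, 0, 1, 1])

    def test_sign_flip_invariance(self):
        L = np.array([[0.8, 0.1], [0.1, 0.9]])
        flipped = L * np.array([1, -1])
        np.testing.assert_array_equal(
            assign_items_from_loadings(L), assign_items_from_loadings(flipped)
        )

    def test_zero_row_warns(self):
        with pytest.warns(RuntimeWarning):
            part = assign_items_from_loadings(np.array([[0.0, 0.0], [0.3, 0.1]]))
        np.testing.assert_array_equal(part, [0, 0])
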