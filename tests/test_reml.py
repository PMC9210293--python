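import warnings

import numpy as np
import pytest
import scipy.linalg

import remlvc as rv
from remlvc import (
    CovariateMatrix,
    ExistenceError,
    InvalidInputError,
    LatentFactors,
    SampleCovariance,
    VarianceComponents,
    build_K,
    log_likelihood,
)
from remlvc.reml import (
    enforce_existence,
    estimate_variance_components,
    fit,
    known_covariate_solution,
    orthogonalize_latents,
    ppca,
    restricted_ppca,
    select_p,
    subspace_split,
)
from conftest import random_psd

E1_3 = np.array([[1.0], [0.0], [0.0]])


class TestSubspaceSplit:
    def test_unit_vector(self):
        s = subspace_split(E1_3)
        np.testing.assert_allclose(s.P1, np.diag([1.0, 0.0, 0.0]), atol=1e-14)
        np.testing.assert_allclose(s.P2, np.diag([0.0, 1.0, 1.0]), atol=1e-14)
        assert s.r == 1

    def test_duplicated_direction_collapses(self):
        Z = np.hstack([E1_3, 2 * E1_3])
        s = subspace_split(Z)
        assert s.r == 1
        np.testing.assert_allclose(s.P1, np.diag([1.0, 0.0, 0.0]), atol=1e-14)

    def test_empty_covariates(self):
        s = subspace_split(CovariateMatrix.empty(4))
        assert s.r == 0
        np.testing.assert_allclose(s.P2, np.eye(4))

    def test_projector_identities(self, rng):
        Z = rng.standard_normal((7, 3))
        s = subspace_split(Z)
        np.testing.assert_allclose(s.P1 + s.P2, np.eye(7), atol=1e-10)
        np.testing.assert_allclose(s.P1 @ s.P2, 0.0, atol=1e-10)
        np.testing.assert_allclose(s.Q1.T @ s.Q2, 0.0, atol=1e-10)


class TestPPCA:
    def test_diagonal_example(self, diag_cov):
        latent, A, sigma2, K = ppca(diag_cov, 1)
        np.testing.assert_allclose(np.abs(latent.values.ravel()), [1.0, 0.0, 0.0], atol=1e-14)
        assert sigma2 == pytest.approx(1.5)
        np.testing.assert_allclose(A, [[2.5]])
        np.testing.assert_allclose(K, np.diag([4.0, 1.5, 1.5]), atol=1e-14)

    def test_no_factors(self, diag_cov):
        _, A, sigma2, K = ppca(diag_cov, 0)
        assert sigma2 == pytest.approx(7.0 / 3.0)
        np.testing.assert_allclose(K, (7.0 / 3.0) * np.eye(3))

    def test_loglik_matches_numeric_maximizer(self, diag_cov):
        # closed form: -log 4 - 2 log 1.5 - 3 (verified against numeric_mle)
        _, _, _, K = ppca(diag_cov, 1)
        L = log_likelihood(K, diag_cov)
        assert L == pytest.approx(-np.log(4) - 2 * np.log(1.5) - 3, abs=1e-10)
        assert L == pytest.approx(-5.1972245773, abs=1e-9)

    def test_p_out_of_range(self, diag_cov):
        with pytest.raises(InvalidInputError):
            ppca(diag_cov, 3)


class TestKnownCovariateSolution:
    def test_informative_covariate(self, diag_cov):
        B, sigma2, K = known_covariate_solution(diag_cov, subspace_split(E1_3))
        assert sigma2 == pytest.approx(1.5)
        np.testing.assert_allclose(B, [[2.5]])
        np.testing.assert_allclose(K, np.diag([4.0, 1.5, 1.5]), atol=1e-14)
        # likelihood agrees with the numeric maximizer over (B, sigma2)
        orc = rv.numeric_mle(diag_cov, E1_3, 0, restarts=5, seed=0)
        assert log_likelihood(K, diag_cov) >= orc.loglik - 1e-6

    def test_noninformative_covariate_fails_existence(self, diag_cov):
        e3 = np.array([[0.0], [0.0], [1.0]])
        with pytest.raises(ExistenceError, match="principal axis"):
            known_covariate_solution(diag_cov, subspace_split(e3))

    def test_empty_covariates_reduce_to_isotropic(self, diag_cov):
        B, sigma2, K = known_covariate_solution(diag_cov, subspace_split(CovariateMatrix.empty(3)))
        assert sigma2 == pytest.approx(7.0 / 3.0)
        np.testing.assert_allclose(K, (7.0 / 3.0) * np.eye(3))

    def test_back_substitution_reconstructs_projection(self, rng):
        Z = rng.standard_normal((6, 2))
        s = subspace_split(Z)
        # make span(Z) informative so the analytic solution exists
        C = SampleCovariance(random_psd(6, rng) + 8.0 * s.P1)
        B, sigma2, K = known_covariate_solution(C, s)
        np.testing.assert_allclose(
            Z @ B @ Z.T + sigma2 * s.P1, s.P1 @ C.values @ s.P1, atol=1e-10
        )


class TestRestrictedPPCA:
    def test_diagonal_case_picks_top_of_complement(self, diag_cov):
        X, spectrum2 = restricted_ppca(diag_cov, subspace_split(E1_3), 1)
        np.testing.assert_allclose(np.abs(X.values.ravel()), [0.0, 1.0, 0.0], atol=1e-14)
        np.testing.assert_allclose(spectrum2, [2.0, 1.0])

    def test_exactly_orthogonal_to_Z(self, diag_cov):
        X, _ = restricted_ppca(diag_cov, subspace_split(E1_3), 1)
        assert np.abs(X.values.T @ E1_3).max() < 1e-14

    def test_random_case_matches_projected_eigenproblem(self, rng):
        """Latent factors equal the dominant eigenvectors of P2 C P2
        restricted to the complement (brute-force oracle)."""
        C = SampleCovariance(random_psd(6, rng))
        Z = rng.standard_normal((6, 2))
        s = subspace_split(Z)
        X, _ = restricted_ppca(C, s, 2)
        M = s.P2 @ C.values @ s.P2
        w, v = np.linalg.eigh(M)
        top = v[:, np.argsort(w)[::-1][:2]]
        # same 2-dimensional subspace
        assert np.abs(scipy.linalg.subspace_angles(X.values, top)).max() < 1e-8
        assert X.check_orthonormal()

    def test_p_too_large(self, diag_cov):
        with pytest.raises(InvalidInputError):
            restricted_ppca(diag_cov, subspace_split(E1_3), 3)


class TestSelectP:
    def test_no_covariates(self, diag_cov4):
        split = subspace_split(CovariateMatrix.empty(4))
        assert select_p(diag_cov4, split, 0.5) == 1  # 4/8
        assert select_p(diag_cov4, split, 0.74) == 2  # 6/8 = 0.75

    def test_known_covariate_counts_toward_target(self, diag_cov4):
        e1 = np.zeros((4, 1))
        e1[0, 0] = 1.0
        assert select_p(diag_cov4, subspace_split(e1), 0.74) == 1  # (4+2)/8

    def test_invalid_rho(self, diag_cov4):
        split = subspace_split(CovariateMatrix.empty(4))
        for rho in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(InvalidInputError):
                select_p(diag_cov4, split, rho)


class TestEnforceExistence:
    def test_informative_covariate_keeps_p(self, diag_cov):
        assert enforce_existence(diag_cov, subspace_split(E1_3), 0) == 0

    def test_weak_covariate_raises_p(self):
        C = SampleCovariance(np.diag([4.0, 1.2, 1.0, 0.9]))
        e2 = np.zeros((4, 1))
        e2[1, 0] = 1.0
        split = subspace_split(e2)
        # sigma2(0) = (4+1+0.9)/3 ~ 1.967 > 1.2; p=1 gives sigma2 = 0.95 < 1.2
        assert enforce_existence(C, split, 0) == 1

    def test_no_covariates_trivially_satisfied(self, diag_cov):
        split = subspace_split(CovariateMatrix.empty(3))
        for p in (0, 1, 2):
            assert enforce_existence(diag_cov, split, p) == p

    def test_unsatisfiable_condition_advises_rescreening(self):
        # covariate along the smallest variance direction, nearly flat rest
        C = SampleCovariance(np.diag([1.0, 1.0, 1.0, 0.1]))
        e4 = np.zeros((4, 1))
        e4[3, 0] = 1.0
        with pytest.raises(ExistenceError, match="reconsidered"):
            enforce_existence(C, subspace_split(e4), 0)


class TestEstimateVarianceComponents:
    def test_diagonal_case(self, diag_cov):
        split = subspace_split(E1_3)
        X = LatentFactors(np.array([[0.0], [1.0], [0.0]]))
        X2, vc = estimate_variance_components(diag_cov, split, X)
        assert vc.sigma2 == pytest.approx(1.0)
        np.testing.assert_allclose(vc.A, [[1.0]])
        np.testing.assert_allclose(vc.B, [[3.0]])
        np.testing.assert_allclose(vc.D, [[0.0]], atol=1e-14)
        K = build_K(E1_3, X2, vc)
        np.testing.assert_allclose(K, np.diag([4.0, 2.0, 1.0]), atol=1e-12)
        orc = rv.numeric_mle(diag_cov, E1_3, 1, restarts=5, seed=1)
        assert log_likelihood(K, diag_cov) >= orc.loglik - 1e-6

    def test_known_latent_cross_covariance_recovered(self):
        c = 0.6
        C = SampleCovariance(np.array([[4.0, c, 0.0], [c, 2.0, 0.0], [0.0, 0.0, 1.0]]))
        split = subspace_split(E1_3)
        X = LatentFactors(np.array([[0.0], [1.0], [0.0]]))
        _, vc = estimate_variance_components(C, split, X)
        np.testing.assert_allclose(vc.D, [[c]], atol=1e-12)

    def test_no_latents_reduces_to_known_covariate_solution(self, diag_cov):
        split = subspace_split(E1_3)
        _, vc = estimate_variance_components(diag_cov, split, LatentFactors.empty(3))
        B_ref, sigma2_ref, _ = known_covariate_solution(diag_cov, split)
        np.testing.assert_allclose(vc.B, B_ref)
        assert vc.sigma2 == pytest.approx(sigma2_ref)


class TestOrthogonalizeLatents:
    def test_full_absorption(self):
        b, a, c = 1.5, 0.8, 0.3
        vc = VarianceComponents(B=[[b]], D=[[c]], A=[[a]], sigma2=1.0)
        Z = np.array([[1.0], [0.0]])
        X_new, vc_new = orthogonalize_latents(Z, Z, vc)
        assert X_new.p == 0
        np.testing.assert_allclose(vc_new.B, [[b + 2 * c + a]], atol=1e-12)
        np.testing.assert_allclose(build_K(Z, X_new, vc_new), build_K(Z, Z, vc), atol=1e-12)

    def test_already_orthogonal_is_fixed_point(self):
        vc = VarianceComponents(B=[[2.0]], D=[[0.5]], A=[[1.0]], sigma2=1.0)
        Z = np.array([[1.0], [0.0], [0.0]])
        X = np.array([[0.0], [1.0], [0.0]])
        X_new, vc_new = orthogonalize_latents(Z, X, vc)
        np.testing.assert_allclose(np.abs(X_new.values), np.abs(X), atol=1e-12)
        np.testing.assert_allclose(build_K(Z, X_new, vc_new), build_K(Z, X, vc), atol=1e-10)

    def test_random_overlap_preserves_K(self, rng):
        n, d, p = 7, 2, 2
        Z = rng.standard_normal((n, d))
        X_raw = rng.standard_normal((n, p)) + Z @ rng.standard_normal((d, p))
        joint = random_psd(d + p, rng) + 0.1 * np.eye(d + p)
        vc = VarianceComponents(
            B=joint[:d, :d], D=joint[:d, d:], A=joint[d:, d:], sigma2=0.9
        )
        # A need not be diagonal on input here; build_K accepts the full block
        X_new, vc_new = orthogonalize_latents(Z, X_raw, vc)
        np.testing.assert_allclose(
            build_K(Z, X_new, vc_new), build_K(Z, X_raw, vc), atol=1e-8
        )
        assert np.abs(X_new.values.T @ Z).max() < 1e-8
        assert np.allclose(vc_new.A, np.diag(np.diag(vc_new.A)))


class TestFit:
    def test_no_covariates_equals_ppca(self, rng):
        Y, _, _ = rv.simulate(
            rv.SimulationSpec(n=20, m=500, components=rv.default_components(0, 2), seed=4)
        )
        C = rv.sample_covariance(Y)
        res = fit(Y, None, p=2)
        latent_ref, A_ref, s2_ref, K_ref = ppca(C, 2)
        np.testing.assert_allclose(res.latent.values, latent_ref.values, atol=1e-10)
        np.testing.assert_allclose(res.components.A, A_ref, atol=1e-10)
        assert res.sigma2 == pytest.approx(s2_ref, abs=1e-12)
        np.testing.assert_allclose(res.K_hat, K_ref, atol=1e-10)

    def test_expression_pcs_as_covariates_yield_next_pcs(self, rng):
        """With the top-d expression PCs as known covariates, the latent
        factors are expression PCs d+1 .. d+p."""
        Y, _, _ = rv.simulate(
            rv.SimulationSpec(n=25, m=800, components=rv.default_components(0, 3), seed=5)
        )
        C = rv.sample_covariance(Y)
        d, p = 3, 2
        res = fit(Y, C.eigenvectors[:, :d], p=p)
        expected = C.eigenvectors[:, d : d + p]
        np.testing.assert_allclose(np.abs(res.latent.values), np.abs(expected), atol=1e-9)

    def test_loglik_shift_identity(self, rng):
        """L(d expression PCs known, p latent) = L(no covariates, d+p latent)."""
        Y, _, _ = rv.simulate(
            rv.SimulationSpec(n=20, m=400, components=rv.default_components(0, 2), seed=6)
        )
        C = rv.sample_covariance(Y)
        for d, p in [(2, 3), (4, 1)]:
            with_z = fit(Y, C.eigenvectors[:, :d], p=p).loglik
            without = fit(Y, None, p=d + p).loglik
            assert with_z == pytest.approx(without, abs=1e-8)

    def test_reconstruction_and_ledger(self, rng):
        Y, Z, _ = rv.simulate(
            rv.SimulationSpec(n=18, m=600, components=rv.default_components(2, 2), seed=7)
        )
        res = fit(Y, Z, rho=0.5)
        np.testing.assert_allclose(
            build_K(Z, res.latent, res.components), res.K_hat, atol=1e-8
        )
        C = rv.sample_covariance(Y)
        # K restricted to span(Z)+span(X) equals the same restriction of C
        G = np.hstack([subspace_split(Z).Q1, res.latent.values])
        np.testing.assert_allclose(G.T @ res.K_hat @ G, G.T @ C.values @ G, atol=1e-9)
        assert res.variance_ledger["variance"].sum() == pytest.approx(C.trace, rel=1e-10)
        assert res.rho_achieved >= 0.5
        assert res.loglik == pytest.approx(sum(res.loglik_terms), abs=1e-9)

    def test_latents_orthogonal_to_covariates(self, rng):
        Y, Z, _ = rv.simulate(
            rv.SimulationSpec(n=15, m=300, components=rv.default_components(3, 2), seed=8)
        )
        res = fit(Y, Z, rho=0.6)
        assert rv.max_abs_cosine(res.latent.values, Z.values) < 1e-10

    def test_p_nonincreasing_in_informative_covariates(self, rng):
        """For fixed rho, adding informative covariates never increases the
        number of latent factors selected."""
        Y, _, _ = rv.simulate(
            rv.SimulationSpec(n=30, m=1000, components=rv.default_components(0, 4), seed=9)
        )
        C = rv.sample_covariance(Y)
        ps = [fit(Y, C.eigenvectors[:, :d] if d else None, rho=0.55).p for d in range(4)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_autocentering_warns(self, rng):
        Y = rng.standard_normal((6, 50)) + 3.0
        with pytest.warns(UserWarning, match="center"):
            fit(Y, None, rho=0.5)

    def test_rho_and_p_are_exclusive(self, rng):
        Y = rng.standard_normal((6, 50))
        with pytest.raises(InvalidInputError):
            fit(Y, None)
        with pytest.raises(InvalidInputError):
            fit(Y, None, rho=0.5, p=1)

    def test_full_rank_covariates_rejected(self, rng):
        Y = rng.standard_normal((5, 50))
        Y -= Y.mean(axis=1, keepdims=True)
        with pytest.raises(ExistenceError, match="span"):
            fit(Y, np.eye(5), rho=0.5)

    def test_minimal_unexplained_variance(self, rng):
        """No random orthonormal p-frame in the complement of span(Z) beats
        the REML factors' residual variance."""
        Y, Z, _ = rv.simulate(
            rv.SimulationSpec(n=12, m=400, components=rv.default_components(2, 2), seed=10)
        )
        C = rv.sample_covariance(Y)
        split = subspace_split(Z)
        res = fit(Y, Z, p=2)
        n, r, p = 12, split.r, 2
        trC1 = np.trace(split.Q1.T @ C.values @ split.Q1)
        for _ in range(100):
            F = split.Q2 @ np.linalg.qr(rng.standard_normal((n - r, p)))[0]
            s2 = (C.trace - trC1 - np.trace(F.T @ C.values @ F)) / (n - r - p)
            assert s2 >= res.sigma2 - 1e-12
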