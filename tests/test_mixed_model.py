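"""REML estimation and BLUP prediction against dense-matrix oracles."""

import numpy as np
import pytest

from hybridgs import (GenotypeMatrix, KinshipMatrix, MixedModelData,
                      blup_predict, compute_dominance_kinship, compute_kinship,
                      eigendecompose, fit_ad_model, fit_gxe_model, fit_reml,
                      restricted_loglik)

from .conftest import (dense_blup, dense_restricted_loglik,
                       golden_section_argmax, random_genotypes, random_kinship)


class TestEigendecompose:
    def test_identity(self):
        K = KinshipMatrix(np.eye(3), list("abc"), 1)
        eig = eigendecompose(K)
        np.testing.assert_allclose(eig.d, np.ones(3))

    def test_rank_one(self):
        K = KinshipMatrix([[1, -1], [-1, 1]], list("ab"), 1)
        eig = eigendecompose(K)
        np.testing.assert_allclose(sorted(eig.d), [0.0, 2.0], atol=1e-12)

    def test_reconstruction(self, rng):
        K = random_kinship(rng, 10)
        eig = eigendecompose(K)
        recon = eig.U @ np.diag(eig.d) @ eig.U.T
        assert np.abs(recon - K.values).max() < 1e-8

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestRestrictedLoglik:
    def test_matches_dense_formula(self, rng):
        for _ in range(5):
            n = 12
            K = random_kinship(rng, n)
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            y = rng.standard_normal(n)
            data = MixedModelData(y=y, K=K, X=X)
            eig = eigendecompose(K)
            for lam in (0.1, 1.0, 10.0):
                rotated = restricted_loglik(lam, data, eig)
                dense = dense_restricted_loglik(lam, y, X, K.values)
                assert abs(rotated - dense) < 1e-8

    def test_lambda_zero_is_ols_case(self, rng):
        n = 10
        K = random_kinship(rng, n)
        y = rng.standard_normal(n)
        data = MixedModelData(y=y, K=K)
        got = restricted_loglik(0.0, data)
        expected = dense_restricted_loglik(0.0, y, np.ones((n, 1)), K.values)
        assert abs(got - expected) < 1e-10

    def test_negative_lambda_rejected(self, rng):
        data = MixedModelData(y=rng.standard_normal(5), K=random_kinship(rng, 5))
        with pytest.raises(ValueError):
            restricted_loglik(-0.5, data)


class TestFitReml:
    def test_newton_matches_grid_search(self, rng):
        """The Newton maximizer agrees with an independent golden-section
        maximizer of the dense likelihood (relative 1e-3, or both at 0)."""
        for _ in range(10):
            n = 30
            K = random_kinship(rng, n)
            g = rng.multivariate_normal(np.zeros(n), K.values)
            y = 1.0 + g + rng.standard_normal(n)
            data = MixedModelData(y=y, K=K)
            fit = fit_reml(data)
            X = data.X

            def f(theta):
                return dense_restricted_loglik(np.exp(theta), y, X, K.values)

            lam_grid = np.exp(golden_section_argmax(f, np.log(1e-8), np.log(1e8)))
            if lam_grid < 1e-6 and fit.lambda_hat < 1e-6:
                continue  # both at the zero boundary
            assert abs(fit.lambda_hat - lam_grid) / lam_grid < 1e-3

    def test_pure_noise_gives_small_lambda(self, rng):
        G = random_genotypes(rng, m=300, n=200, codes=(-1.0, 0.0, 1.0))
        K = compute_kinship(G)
        lams = []
        for _ in range(20):
            y = rng.standard_normal(200)
            lams.append(fit_reml(MixedModelData(y=y, K=K)).lambda_hat)
        assert np.median(lams) < 0.1

    def test_recovers_known_variance_ratio(self, rng):
        """lambda = 2 simulations at n = 200: median estimate in [1, 4]."""
        lams = []
        for _ in range(7):
            K = random_kinship(rng, 200, m=400)
            L = np.linalg.cholesky(K.values + 1e-10 * np.eye(200))
            g = L @ rng.standard_normal(200) * np.sqrt(2.0)
            y = g + rng.standard_normal(200)
            lams.append(fit_reml(MixedModelData(y=y, K=K)).lambda_hat)
        assert 1.0 <= np.median(lams) <= 4.0

    def test_constant_phenotype_flagged(self, rng):
        K = random_kinship(rng, 8)
        with pytest.raises(ValueError):
            fit_reml(MixedModelData(y=np.ones(8), K=K))

    def test_phi2_consistency(self, rng):
        K = random_kinship(rng, 25)
        y = rng.standard_normal(25)
        fit = fit_reml(MixedModelData(y=y, K=K))
        assert fit.phi2_hat == fit.lambda_hat * fit.sigma2_hat
        assert fit.lambda_hat >= 0 and fit.sigma2_hat > 0


class TestBlupPredict:
    def _split(self, rng, n1=15, n2=5, m=40):
        G = random_genotypes(rng, m=m, n=n1 + n2,
                             codes=(-1.0, -0.5, 0.0, 0.5, 1.0))
        K = compute_kinship(G)
        ids = G.individual_ids
        return K, ids[:n1], ids[n1:]

    def test_matches_dense_solve(self, rng):
        K, train_ids, test_ids = self._split(rng)
        y1 = rng.standard_normal(len(train_ids))
        data = MixedModelData(y=y1, K=K.submatrix(train_ids))
        fit = fit_reml(data)
        K21 = K.block(test_ids, train_ids)
        pred = blup_predict(fit, data, K21, hybrid_ids=test_ids)
        dense = dense_blup(fit.lambda_hat, y1, data.X, fit.beta_hat,
                           K.submatrix(train_ids).values, K21,
                           np.ones((len(test_ids), 1)))
        assert np.abs(pred.y_hat[:, 0] - dense).max() < 1e-10

    def test_zero_lambda_predicts_fixed_effects_only(self, rng):
        K, train_ids, test_ids = self._split(rng)
        y1 = rng.standard_normal(len(train_ids))
        data = MixedModelData(y=y1, K=K.submatrix(train_ids))
        fit = fit_reml(data)
        fit.lambda_hat = 0.0
        pred = blup_predict(fit, data, K.block(test_ids, train_ids))
        np.testing.assert_allclose(pred.y_hat[:, 0], fit.beta_hat[0])

    def test_in_sample_prediction_tracks_observations(self, rng):
        # low-rank kinship (m < n) so the variance ratio is well identified
        K, train_ids, _ = self._split(rng, n1=30, n2=1, m=10)
        K11 = K.submatrix(train_ids)
        g = np.linalg.cholesky(K11.values + 1e-8 * np.eye(30)) @ rng.standard_normal(30)
        y1 = 3.0 * g + rng.standard_normal(30)
        data = MixedModelData(y=y1, K=K11)
        fit = fit_reml(data)
        pred = blup_predict(fit, data, K11.values, hybrid_ids=train_ids)
        r = np.corrcoef(y1, pred.y_hat[:, 0])[0, 1]
        assert r > 0.5

    def test_invariant_to_training_permutation(self, rng):
        K, train_ids, test_ids = self._split(rng)
        y1 = rng.standard_normal(len(train_ids))
        data = MixedModelData(y=y1, K=K.submatrix(train_ids))
        fit = fit_reml(data)
        K21 = K.block(test_ids, train_ids)
        base = blup_predict(fit, data, K21).y_hat

        perm = rng.permutation(len(train_ids))
        ids_p = [train_ids[i] for i in perm]
        data_p = MixedModelData(y=y1[perm], K=K.submatrix(ids_p))
        fit_p = fit_reml(data_p)
        K21_p = K.block(test_ids, ids_p)
        permuted = blup_predict(fit_p, data_p, K21_p).y_hat
        np.testing.assert_allclose(permuted, base, atol=1e-8)

    def test_shape_mismatch_rejected(self, rng):
        K, train_ids, test_ids = self._split(rng)
        data = MixedModelData(y=rng.standard_normal(len(train_ids)),
                              K=K.submatrix(train_ids))
        fit = fit_reml(data)
        with pytest.raises(ValueError, match="training columns"):
            blup_predict(fit, data, np.ones((3, 7)))


class TestAdditiveDominanceModel:
    def test_zero_dominance_kernel_reduces_to_additive(self, rng):
        K = random_kinship(rng, 20)
        y = rng.standard_normal(20)
        data = MixedModelData(y=y, K=K)
        add = fit_reml(data)
        KD0 = KinshipMatrix(np.zeros((20, 20)), K.individual_ids, K.n_markers_used)
        ad = fit_ad_model(data, KD0)
        assert abs(ad.restricted_loglik - add.restricted_loglik) < 1e-10
        assert ad.lambda_d == 0.0

    def test_nested_likelihood_never_worse(self, rng):
        G = random_genotypes(rng, m=40, n=25, codes=(-1.0, 0.0, 1.0))
        K = compute_kinship(G)
        KD = compute_dominance_kinship(G)
        y = rng.standard_normal(25)
        data = MixedModelData(y=y, K=K)
        add = fit_reml(data)
        ad = fit_ad_model(data, KD)
        assert ad.restricted_loglik >= add.restricted_loglik - 1e-9

    def test_recovers_small_dominance_when_absent(self, rng):
        """Simulated without dominance: lambda_D stays small and lambda_A
        tracks the additive-only estimate (median over seeds)."""
        ratios, lam_ds = [], []
        for s in range(5):
            r = np.random.default_rng(100 + s)
            G = random_genotypes(r, m=200, n=120, codes=(-1.0, 0.0, 1.0))
            K = compute_kinship(G)
            KD = compute_dominance_kinship(G)
            L = np.linalg.cholesky(K.values + 1e-10 * np.eye(120))
            y = L @ r.standard_normal(120) * np.sqrt(2.0) + r.standard_normal(120)
            data = MixedModelData(y=y, K=K)
            add = fit_reml(data)
            ad = fit_ad_model(data, KD)
            ratios.append(ad.lambda_a / max(add.lambda_hat, 1e-8))
            lam_ds.append(ad.lambda_d)
        assert 0.5 <= np.median(ratios) <= 1.5
        assert np.median(lam_ds) < 0.5 * np.median([max(r, 1e-8) for r in ratios])


class TestGxEModel:
    def test_single_environment_reduces_to_additive(self, rng):
        K = random_kinship(rng, 15)
        y = rng.standard_normal((15, 1))
        gfit = fit_gxe_model(y, K)
        add = fit_reml(MixedModelData(y=y[:, 0], K=K))
        assert abs(gfit.restricted_loglik - add.restricted_loglik) < 1e-10
        assert gfit.lambda_gxe == 0.0

    def test_identical_environments_have_no_interaction(self, rng):
        K = random_kinship(rng, 12)
        y = rng.standard_normal(12)
        gfit = fit_gxe_model(np.column_stack([y, y]), K)
        assert gfit.lambda_gxe <= 1e-6

    def test_likelihood_matches_dense_kronecker(self, rng):
        n, E = 10, 2
        K = random_kinship(rng, n)
        Y = rng.standard_normal((n, E))
        gfit = fit_gxe_model(Y, K)
        y = Y.T.ravel()
        X = np.kron(np.eye(E), np.ones((n, 1)))
        V0 = (gfit.lambda_main * np.kron(np.ones((E, E)), K.values)
              + gfit.lambda_gxe * np.kron(np.eye(E), K.values) + np.eye(n * E))
        Vinv = np.linalg.inv(V0)
        C = X.T @ Vinv @ X
        beta = np.linalg.solve(C, X.T @ Vinv @ y)
        r = y - X @ beta
        s2 = float(r @ Vinv @ r) / (n * E - E)
        dense = (-0.5 * np.linalg.slogdet(V0)[1] - 0.5 * np.linalg.slogdet(C)[1]
                 - 0.5 * (n * E - E) * np.log(s2))
        assert abs(dense - gfit.restricted_loglik) < 1e-8

    def test_no_gxe_simulation_gives_small_interaction(self):
        from hybridgs import SimulationConfig, make_training_and_test

        cfg = SimulationConfig(n_parents=30, m_markers=200, n_train_hybrids=150,
                               n_test_hybrids=2, h2_target=0.7, gxe_share=0.0,
                               n_environments=2, seed=4)
        b = make_training_and_test(cfg, design="shared")
        K = b.K.submatrix(b.train.individual_ids)
        gfit = fit_gxe_model(b.pheno_train.to_numpy(), K)
        assert gfit.lambda_gxe < 0.25 * max(gfit.lambda_main, 1e-8)

    def test_mismatched_dimensions_rejected(self, rng):
        K = random_kinship(rng, 8)
        with pytest.raises(ValueError):
            fit_gxe_model(rng.standard_normal((9, 2)), K)
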