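import numpy as np
import pytest

from reda.assoc import (
    association_test,
    empirical_fdr,
    global_test,
    local_coefficients,
    nam_pca,
    residualize,
)


def _random_qt(n=10, m=40, seed=0):
    rng = np.random.default_rng(seed)
    return residualize(rng.random((n, m)))


class TestResidualize:
    def test_no_covariates_centered_unit_variance(self):
        Qt = _random_qt()
        np.testing.assert_allclose(Qt.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Qt.std(axis=0), 1, atol=1e-12)

    def test_covariate_equal_to_column_kills_it(self):
        rng = np.random.default_rng(1)
        Q = rng.random((8, 5))
        Qt = residualize(Q, covariates=Q[:, 2:3])
        np.testing.assert_allclose(Qt[:, 2], 0, atol=1e-8)

    def test_orthogonal_covariate_is_noop(self):
        rng = np.random.default_rng(2)
        Q = rng.random((9, 6))
        Qc = Q - Q.mean(axis=0)
        # build a covariate orthogonal to every centered column (and to 1)
        basis, _ = np.linalg.qr(np.hstack([np.ones((9, 1)), Qc]))
        null_space = np.eye(9) - basis @ basis.T
        cov = null_space @ rng.random(9)
        np.testing.assert_allclose(
            residualize(Q, covariates=cov[:, None]), residualize(Q), atol=1e-10
        )

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(3)
        Q = rng.random((8, 4))
        cov = np.ones((8, 1))  # collinear with intercept
        with pytest.raises(ValueError, match="rank-deficient"):
            residualize(Q, covariates=cov)

    def test_zero_variance_column_left_at_zero(self):
        Q = np.random.default_rng(4).random((6, 3))
        Q[:, 1] = 0.25
        Qt = residualize(Q)
        np.testing.assert_array_equal(Qt[:, 1], 0)


class TestNamPca:
    def test_rank_one_matrix_single_component(self):
        u = np.array([1.0, -1, 2, 0, -2])
        v = np.random.default_rng(0).random(12)
        scores, V, svals = nam_pca(np.outer(u, v))
        assert (svals > 1e-10).sum() == 1
        c = np.corrcoef(scores[:, 0], u)[0, 1]
        assert abs(c) == pytest.approx(1.0, abs=1e-10)

    def test_sign_convention_largest_loading_positive(self):
        scores, V, svals = nam_pca(_random_qt(seed=5))
        for j in range(V.shape[1]):
            assert V[np.abs(V[:, j]).argmax(), j] > 0

    def test_two_samples_one_informative_component(self):
        Qt = residualize(np.random.default_rng(6).random((2, 10)))
        scores, V, svals = nam_pca(Qt)
        assert svals.size == 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="non-degenerate"):
            nam_pca(np.zeros((5, 8)))


class TestGlobalTest:
    def test_perfect_association_attains_permutation_floor(self):
        scores, V, svals = nam_pca(_random_qt(seed=7))
        y = scores[:, 0].copy()
        p, k, r2, _ = global_test(scores, y, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)
        assert k == 1
        assert r2[0] == pytest.approx(1.0, abs=1e-10)

    def test_null_phenotype_p_roughly_uniform(self):
        # Monte-Carlo calibration: with random y the p-value should be
        # uniform; check the rejection rate at 0.05 over 60 draws
        scores, V, svals = nam_pca(_random_qt(n=12, m=60, seed=8))
        rng = np.random.default_rng(9)
        rejections = 0
        n_draws = 60
        for i in range(n_draws):
            y = rng.normal(size=12)
            p, *_ = global_test(scores, y, n_perm=199, seed=i)
            rejections += p < 0.05
        # binomial(60, 0.05): central 99.9% region is [0, 10]
        assert rejections <= 10

    def test_kmax_one_reduces_to_plain_permutation_test(self):
        scores, V, svals = nam_pca(_random_qt(seed=10))
        y = np.random.default_rng(11).normal(size=10)
        p, k, r2, det = global_test(scores, y, k_max=1, n_perm=499, seed=2)
        # plain permutation test of R2_1 computed independently
        yc = y - y.mean()
        u1 = scores[:, 0] / np.linalg.norm(scores[:, 0])
        r2_obs = (u1 @ yc) ** 2 / (yc @ yc)
        perms = det["perms"]
        r2_perm = (perms @ u1) ** 2 / (yc @ yc)
        p_plain = (1 + (r2_perm >= r2_obs - 1e-12).sum()) / (1 + 499)
        assert p == pytest.approx(p_plain)
        assert k == 1

    def test_floor_bound_and_relabel_invariance(self):
        scores, V, svals = nam_pca(_random_qt(seed=12))
        y = np.random.default_rng(13).normal(size=10)
        p, *_ = global_test(scores, y, n_perm=999, seed=3)
        assert p >= 1 / 1000
        # permuting samples jointly leaves p unchanged
        perm = np.random.default_rng(14).permutation(10)
        p2, *_ = global_test(scores[perm], y[perm], n_perm=999, seed=3)
        assert p2 == pytest.approx(p, abs=0.1)

    def test_constant_phenotype_rejected(self):
        scores, V, svals = nam_pca(_random_qt(seed=15))
        with pytest.raises(ValueError, match="no variation"):
            global_test(scores, np.ones(10), n_perm=100, seed=0)

    def test_batch_stratified_permutations_stay_within_batch(self):
        from reda.assoc import _permute_within_batch

        y = np.arange(8.0)
        batch = np.array(["a"] * 4 + ["b"] * 4)
        rng = np.random.default_rng(0)
        perms = _permute_within_batch(y, batch, 50, rng)
        assert (np.sort(perms[:, :4], axis=1) == np.arange(4.0)).all()
        assert (np.sort(perms[:, 4:], axis=1) == np.arange(4.0, 8.0)).all()


class TestLocalCoefficients:
    def test_column_equal_to_phenotype_full_rank(self):
        rng = np.random.default_rng(16)
        y = rng.normal(size=8)
        Qt = rng.normal(size=(8, 5))
        Qt[:, 3] = y - y.mean()
        Qt = Qt - Qt.mean(axis=0)
        scores, V, svals = nam_pca(Qt)
        coefs = local_coefficients(Qt, V, svals, y, k_selected=svals.size)
        assert coefs[3] == pytest.approx(1.0, abs=1e-10)

    def test_column_orthogonal_to_subspace_gets_zero(self):
        # rank-2 structure plus a column orthogonal to the top-1 subspace
        u1 = np.array([1.0, -1, 1, -1, 1, -1])
        u2 = np.array([1.0, 1, -1, -1, 0, 0])
        Qt = np.column_stack([3 * u1, 3 * u1, u2])
        scores, V, svals = nam_pca(Qt)
        y = u1 + 0.1 * u2
        coefs = local_coefficients(Qt, V, svals, y, k_selected=1)
        assert abs(coefs[2]) < 1e-10

    def test_three_sample_brute_force_oracle(self):
        # N=3, M=4: coefficient must equal corr(y, P_k q_i) computed with
        # explicit projector algebra
        Qt = np.array(
            [[1.0, -0.5, 0.2, 0.0], [-1.0, 1.5, -0.1, 0.3], [0.0, -1.0, -0.1, -0.3]]
        )
        Qt = Qt - Qt.mean(axis=0)
        y = np.array([2.0, -1.0, -1.0])
        scores, V, svals = nam_pca(Qt)
        k = 1
        coefs = local_coefficients(Qt, V, svals, y, k_selected=k)
        u, s, vt = np.linalg.svd(Qt, full_matrices=False)
        P = u[:, :k] @ u[:, :k].T
        yc = y - y.mean()
        for i in range(4):
            q_hat = P @ Qt[:, i]
            if np.linalg.norm(q_hat) < 1e-12:
                expect = 0.0
            else:
                expect = (yc @ q_hat) / (np.linalg.norm(yc) * np.linalg.norm(q_hat))
            assert coefs[i] == pytest.approx(expect, abs=1e-10)

    def test_bounds_and_y_scaling_invariance(self):
        Qt = _random_qt(seed=17)
        scores, V, svals = nam_pca(Qt)
        y = np.random.default_rng(18).normal(size=10)
        c1 = local_coefficients(Qt, V, svals, y, 3)
        assert np.abs(c1).max() <= 1.0
        c2 = local_coefficients(Qt, V, svals, 7.5 * y, 3)
        np.testing.assert_allclose(c1, c2, atol=1e-12)
        c3 = local_coefficients(Qt, V, svals, -y, 3)
        np.testing.assert_allclose(c1, -c3, atol=1e-12)

    def test_k_beyond_available_components_rejected(self):
        Qt = _random_qt(seed=19)
        scores, V, svals = nam_pca(Qt)
        with pytest.raises(ValueError, match="exceeds"):
            local_coefficients(Qt, V, svals, np.arange(10.0), svals.size + 1)


class TestEmpiricalFdr:
    def test_table_monotone_and_threshold_grid_spans_observed(self):
        Qt = _random_qt(n=12, m=50, seed=20)
        scores, V, svals = nam_pca(Qt)
        y = np.random.default_rng(21).normal(size=12)
        coefs = local_coefficients(Qt, V, svals, y, 2)
        table, t_star, passing = empirical_fdr(
            coefs, Qt, V, svals, y, n_perm=199, seed=4
        )
        ts = np.array([t for t, _ in table])
        fs = np.array([f for _, f in table])
        assert (np.diff(ts) > 0).all()
        assert (np.diff(fs) <= 1e-12).all()  # monotone non-increasing
        assert fs.min() >= 0 and fs.max() <= 1
        assert ts.max() == pytest.approx(np.abs(coefs).max())

    def test_null_observed_passes_almost_nothing(self):
        # observed coefficients drawn from the null: with the hierarchical
        # gate on the global test, the FDR-5% passing fraction is ~0
        rng = np.random.default_rng(22)
        fracs = []
        for i in range(25):
            Qt = _random_qt(n=10, m=60, seed=100 + i)
            scores, V, svals = nam_pca(Qt)
            y = rng.normal(size=10)
            p, k, _, det = global_test(scores, y, n_perm=199, seed=i)
            coefs = local_coefficients(Qt, V, svals, y, k)
            _, _, passing = empirical_fdr(
                coefs, Qt, V, svals, y, n_perm=199, seed=i, _details=det
            )
            fracs.append(passing.mean() if p <= 0.05 else 0.0)
        assert np.mean(fracs) <= 0.05

    def test_no_threshold_reaches_fdr_gives_empty_set(self):
        Qt = _random_qt(seed=23)
        scores, V, svals = nam_pca(Qt)
        y = np.random.default_rng(24).normal(size=10)
        coefs = local_coefficients(Qt, V, svals, y, 2)
        table, t_star, passing = empirical_fdr(
            coefs, Qt, V, svals, y, n_perm=199, seed=5, fdr=1e-9
        )
        assert t_star is None and passing.sum() == 0


class TestAssociationTest:
    def test_rejects_fewer_than_four_samples(self, toy_samples):
        from reda.nam import Nam

        nam = Nam(
            Q=np.full((2, 4), 0.25),
            R_raw=np.full((2, 4), 0.5),
            sample_ids=["s1", "s2"],
            cell_barcodes=["c1", "c2", "c3", "c4"],
            s_selected=1,
            alpha=0.3,
        )
        with pytest.raises(ValueError, match="4 samples"):
            association_test(nam, toy_samples, n_perm=100, seed=0)
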