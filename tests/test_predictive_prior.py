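import numpy as np
import pytest

from perfcad.predictive_prior import (
    RegressionDesign,
    build_predictive_prior,
    fit_reduced_ols,
    pca_highdim,
    pca_regression,
    rescale_beta,
)


def covariance_eigh_oracle(X, K):
    """Brute-force eigendecomposition of the J x J biased covariance."""
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / X.shape[0]
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    return evals[order][:K], evecs[:, order][:, :K]


def min_norm_ls_oracle(X, y):
    """Minimum-norm least squares on the centered design via pseudoinverse."""
    Xc = X - X.mean(axis=0)
    return np.linalg.pinv(Xc) @ y


class TestPCAHighdim:
    def test_rank_one(self):
        a = np.array([3.0, 0.0, 4.0, 0.0, 0.0])
        X = np.stack([a, -a])
        U, lambdas, V = pca_highdim(X, K=1)
        np.testing.assert_allclose(np.abs(U[:, 0]), np.abs(a) / 5.0, atol=1e-12)
        assert np.linalg.norm(U[:, 0]) == pytest.approx(1.0)
        assert lambdas[0] > 0

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 300))
        K = 5
        U, lambdas, _ = pca_highdim(X, K)
        ev_oracle, evec_oracle = covariance_eigh_oracle(X, K)
        np.testing.assert_allclose(lambdas, ev_oracle, atol=1e-8)
        for k in range(K):
            dot = abs(U[:, k] @ evec_oracle[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)  # equal up to sign

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 120))
        Xc = X - X.mean(axis=0)
        U, _, _ = pca_highdim(X, K=7)
        np.testing.assert_allclose(Xc @ U @ U.T, Xc, atol=1e-8)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            pca_highdim(np.random.default_rng(0).normal(size=(4, 50)), K=4)

    def test_degenerate_eigenvalues_reduce_k(self):
        # two identical rows after centering leave rank 1
        row = np.arange(10.0)
        X = np.stack([row, row, -row, -row])
        with pytest.warns(RuntimeWarning, match="reduced K"):
            U, lambdas, _ = pca_highdim(X, K=3)
        assert len(lambdas) == 1
        assert U.shape[1] == 1


class TestReducedOLS:
    def test_exact_1d(self):
        beta = fit_reduced_ols(np.array([[-1.0], [1.0]]), np.array([-1.0, 1.0]))
        np.testing.assert_allclose(beta, [1.0])

    def test_orthogonal_target_zero(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        y = np.zeros(4)
        np.testing.assert_allclose(fit_reduced_ols(X, y), [0.0, 0.0], atol=1e-12)

    def test_matches_pinv_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        np.testing.assert_allclose(
            fit_reduced_ols(X, y), np.linalg.pinv(X) @ y, atol=1e-10
        )

    def test_rank_deficient_falls_back(self):
        X = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        y = np.array([1.0, 2.0, 3.0])
        beta = fit_reduced_ols(X, y)
        np.testing.assert_allclose(X @ beta, y, atol=1e-8)


class TestRegressionDesign:
    def test_rejects_single_class(self):
        with pytest.raises(ValueError, match="both classes"):
            RegressionDesign(
                X=np.ones((3, 4)), y=np.array([1.0, 1.0, 1.0]), subject_ids=list("abc")
            )

    def test_group_coding(self):
        from perfcad.comparison import ScoreMap

        Ls = [ScoreMap(np.full(3, 0.5), kind="likelihood", subject_id=s) for s in "abc"]
        d = RegressionDesign.from_likelihoods(Ls, ["HC", "AD_EA", "AD_LA"])
        np.testing.assert_allclose(d.y, [-1.0, 1.0, 1.0])


class TestBuildPrior:
    def test_planted_block_attains_max(self):
        # AD rows carry +delta on one voxel block: prior peaks inside it
        rng = np.random.default_rng(42)
        n, j = 20, 300
        block = slice(100, 140)
        X = rng.normal(0.5, 0.02, size=(n, j))
        y = np.array([-1.0] * 10 + [1.0] * 10)
        X[10:, block] += 0.3
        design = RegressionDesign(X=X, y=y, subject_ids=[f"s{i}" for i in range(n)])
        prior = build_predictive_prior(design, K=10)
        assert prior.values.min() == 0.0 and prior.values.max() == 1.0
        assert 100 <= int(np.argmax(prior.values)) < 140
        inside = prior.values[block].mean()
        outside = np.concatenate([prior.values[:100], prior.values[140:]]).mean()
        assert inside > outside + 0.3

    def test_constant_column_gets_zero_weight(self):
        rng = np.random.default_rng(3)
        n, j = 12, 60
        X = rng.normal(size=(n, j))
        X[:, 7] = 2.5  # zero variance; centering kills it
        y = np.array([-1.0, 1.0] * 6)
        design = RegressionDesign(X=X, y=y, subject_ids=[f"s{i}" for i in range(n)])
        result = pca_regression(design, K=8)
        assert result.beta_full[7] == pytest.approx(0.0, abs=1e-10)

    def test_exclusion_changes_prior(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 80))
        y = np.array([-1.0] * 5 + [1.0] * 5)
        design = RegressionDesign(X=X, y=y, subject_ids=[f"s{i}" for i in range(10)])
        full = build_predictive_prior(design, K=5)
        loo = build_predictive_prior(design, K=5, exclude=["s0"])
        assert not np.allclose(full.values, loo.values)

    def test_single_class_after_exclusion_fatal(self):
        X = np.random.default_rng(0).normal(size=(4, 20))
        y = np.array([-1.0, -1.0, -1.0, 1.0])
        design = RegressionDesign(X=X, y=y, subject_ids=list("abcd"))
        with pytest.raises(ValueError, match="both classes"):
            build_predictive_prior(design, K=2, exclude=["d"])

    def test_prior_spans_unit_interval(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(9, 100))
        y = np.array([-1.0] * 4 + [1.0] * 5)
        design = RegressionDesign(X=X, y=y, subject_ids=[f"s{i}" for i in range(9)])
        prior = build_predictive_prior(design, K=6)
        assert prior.values.min() == 0.0
        assert prior.values.max() == 1.0
        assert prior.kind == "prior"


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_full_k_equals_min_norm_solution(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        j = int(rng.integers(n + 1, 501))
        X = rng.normal(size=(n, j))
        y = np.where(rng.random(n) > 0.5, 1.0, -1.0)
        if len(set(y)) == 1:
            y[0] = -y[0]
        design = RegressionDesign(X=X, y=y, subject_ids=[f"s{i}" for i in range(n)])
        result = pca_regression(design, K=n - 1)
        np.testing.assert_allclose(
            result.beta_full, min_norm_ls_oracle(X, y), atol=1e-6
        )

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 100))
        y = np.where(rng.random(8) > 0.5, 1.0, -1.0)
        y[:2] = [-1.0, 1.0]
        Xc = X - X.mean(axis=0)
        U, lambdas, V = pca_highdim(X, K=5)
        beta_ref = U @ fit_reduced_ols(Xc @ U, y)
        flip = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        U2 = U * flip
        beta_flip = U2 @ fit_reduced_ols(Xc @ U2, y)
        np.testing.assert_allclose(beta_ref, beta_flip, atol=1e-10)


def test_rescale_methods():
    beta = np.array([-2.0, 0.0, 2.0])
    np.testing.assert_allclose(rescale_beta(beta, "minmax"), [0.0, 0.5, 1.0])
    np.testing.assert_allclose(rescale_beta(beta, "abs"), [1.0, 0.0, 1.0])
    np.testing.assert_allclose(rescale_beta(beta, "clip"), [0.0, 0.0, 1.0])
    np.testing.assert_allclose(rescale_beta(np.zeros(3), "minmax"), [0.5, 0.5, 0.5])
    with pytest.raises(ValueError):
        rescale_beta(beta, "nope")
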