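import numpy as np
import pytest
from sklearn.base import clone

from toxdeconv.deconvolution import (
    DRUG_RESPONDING,
    ENVIRONMENTAL,
    NMFConfig,
    PostModifiedNMF,
    _als_iterate,
    _als_kernel,
    als_nmf,
    label_components,
    multi_restart_deconvolute,
    normalize_weights,
    refit_signatures,
)
from toxdeconv.errors import ConfigError, DataError
from toxdeconv.synthetic import SyntheticConfig, generate_compound

from conftest import make_compound_dataset


def random_rank2(m=200, n=6, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    W = rng.lognormal(0, 0.5, size=(m, 2))
    H = rng.dirichlet([2.0, 2.0], size=n).T
    V = W @ H
    if noise:
        V = V * np.exp(rng.normal(0, noise, size=V.shape))
    return V, W, H


class TestAlsNmf:
    def test_exact_rank_one(self):
        rng = np.random.default_rng(0)
        V = np.outer(rng.random(50) + 0.1, rng.random(4) + 0.1)
        _, _, rmse = als_nmf(V, k=1, max_iter=1000, tol=1e-12, seed=0)
        assert rmse <= 1e-6

    def test_exact_rank_two_best_of_restarts(self):
        V, _, _ = random_rank2(m=500, n=6, seed=1)
        rng = np.random.default_rng(1)
        best = min(
            als_nmf(V, k=2, max_iter=1000, tol=1e-12, seed=rng)[2] for _ in range(50)
        )
        assert best <= 1e-4

    def test_fixed_seed_bitwise_deterministic(self):
        V, _, _ = random_rank2(seed=2, noise=0.05)
        W1, H1, r1 = als_nmf(V, k=2, seed=42)
        W2, H2, r2 = als_nmf(V, k=2, seed=42)
        np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(H1, H2)
        assert r1 == r2

    def test_outputs_nonnegative(self):
        V, _, _ = random_rank2(seed=3, noise=0.1)
        W, H, _ = als_nmf(V, k=2, seed=0)
        assert W.min() >= 0 and H.min() >= 0

    def test_k_not_smaller_than_n_rejected(self):
        with pytest.raises(ConfigError, match="smaller than"):
            als_nmf(np.ones((10, 2)), k=2)

    def test_all_zero_rejected(self):
        with pytest.raises(DataError, match="zero"):
            als_nmf(np.zeros((10, 4)), k=2)

    def test_kernel_matches_numpy_reference(self):
        """The jitted loop-explicit kernel and the numpy path agree."""
        rng = np.random.default_rng(4)
        A = rng.random((40, 5))
        W0 = (1.0 - rng.random((40, 2))) * A.mean()
        Wk, Hk, lk, fk, ik = _als_kernel(A.copy(), W0.copy(), 80, 1e-10)
        Wn, Hn, ln, fn, it = _als_iterate(A.copy(), W0.copy(), 80, 1e-10)
        assert (fk, ik) == (fn, it)
        np.testing.assert_allclose(Wk, Wn, atol=1e-9)
        np.testing.assert_allclose(Hk, Hn, atol=1e-9)
        assert abs(lk - ln) < 1e-9


class TestNormalizeWeights:
    def test_hand_example(self):
        H = np.array([[2.0, 1.0], [2.0, 3.0]])
        np.testing.assert_allclose(
            normalize_weights(H), [[0.5, 0.25], [0.5, 0.75]]
        )

    def test_idempotent_and_sums_to_one(self):
        rng = np.random.default_rng(5)
        H = rng.random((3, 7)) + 0.01
        Hs = normalize_weights(H)
        np.testing.assert_allclose(Hs.sum(axis=0), 1.0, atol=1e-12)
        np.testing.assert_allclose(normalize_weights(Hs), Hs)

    def test_zero_sum_column_names_sample(self):
        H = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(DataError, match="sampleX"):
            normalize_weights(H, sample_ids=["s0", "sampleX"])


class TestRefitSignatures:
    def test_identity_weights_return_v(self):
        rng = np.random.default_rng(6)
        V = rng.random((10, 2))
        W, neg = refit_signatures(V, np.eye(2))
        np.testing.assert_allclose(W, V, atol=1e-12)
        assert neg == 0.0

    def test_exact_recovery(self):
        rng = np.random.default_rng(7)
        W_true = rng.random((50, 2)) + 0.05
        H = normalize_weights(rng.random((2, 6)) + 0.05)
        W, neg = refit_signatures(W_true @ H, H)
        np.testing.assert_allclose(W, W_true, atol=1e-8)
        assert neg == 0.0

    def test_matches_per_gene_least_squares_oracle(self):
        rng = np.random.default_rng(8)
        V = rng.random((30, 6))
        H = normalize_weights(rng.random((2, 6)) + 0.05)
        W, _ = refit_signatures(V, H, clamp_negatives=False)
        for g in range(V.shape[0]):  # independent per-gene normal equations
            w_g, *_ = np.linalg.lstsq(H.T, V[g], rcond=None)
            np.testing.assert_allclose(W[g], w_g, atol=1e-8)

    def test_singular_weights_rejected(self):
        V = np.random.default_rng(9).random((10, 4))
        H = np.tile([[0.5], [0.5]], 4)
        with pytest.raises(DataError, match="singular"):
            refit_signatures(V, H)


class TestLabelComponents:
    def test_perfect_correlation_is_environmental(self):
        rng = np.random.default_rng(10)
        ctrl = rng.random(30)
        W = np.column_stack([ctrl, rng.random(30)])
        labels, corrs = label_components(W, ctrl)
        assert labels == [ENVIRONMENTAL, DRUG_RESPONDING]
        assert corrs[0] == pytest.approx(1.0)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(11)
        ctrl = rng.random(30)
        W = np.column_stack([ctrl, rng.random(30)])
        l1, _ = label_components(W, ctrl)
        l2, _ = label_components(W[:, ::-1], ctrl)
        assert l1 == l2[::-1]

    def test_zero_variance_column_warned_drug(self):
        ctrl = np.random.default_rng(12).random(20)
        W = np.column_stack([np.ones(20), ctrl])
        with pytest.warns(UserWarning, match="zero-variance"):
            labels, _ = label_components(W, ctrl)
        assert labels[0] == DRUG_RESPONDING

    def test_k_not_two_rejected(self):
        with pytest.raises(ConfigError, match="k = 2"):
            label_components(np.ones((5, 3)), np.ones(5))


class TestMultiRestart:
    def test_degenerate_config_equals_single_chain(self):
        """repeats=1, restarts=1 reproduces als_nmf -> normalize -> refit."""
        V, _, _ = random_rank2(m=100, seed=13, noise=0.05)
        ds = make_compound_dataset(V, V[:, :2] + 0.1)
        cfg = NMFConfig(k=2, restarts=1, repeats=1, seed=3)
        res = multi_restart_deconvolute(ds, cfg)
        W, H, _ = als_nmf(V, 2, max_iter=cfg.max_iter, tol=cfg.tol, seed=3)
        H_star = normalize_weights(H)
        W_star, neg = refit_signatures(V, H_star)
        np.testing.assert_array_equal(res.W_star, W_star)
        np.testing.assert_array_equal(res.H_star, H_star)
        assert res.negative_fraction == neg

    def test_result_invariants_and_determinism(self):
        dv, _, _ = generate_compound(SyntheticConfig(n_genes=400, seed=14), "C", 14)
        cfg = NMFConfig(k=2, restarts=6, repeats=3, seed=14)
        res = multi_restart_deconvolute(dv, cfg)
        np.testing.assert_allclose(res.H_star.sum(axis=0), 1.0, atol=1e-9)
        assert res.W_star.min() >= 0 and res.H_star.min() >= 0
        assert set(res.labels) == {ENVIRONMENTAL, DRUG_RESPONDING}
        assert 0 <= res.negative_fraction <= 1
        # selected minimum never exceeds the median restart
        assert np.all(
            res.restart_rmse.min(axis=1) <= np.median(res.restart_rmse, axis=1)
        )
        res2 = multi_restart_deconvolute(dv, cfg)
        np.testing.assert_array_equal(res.W_star, res2.W_star)
        np.testing.assert_array_equal(res.H_star, res2.H_star)
        assert res.rmse == res2.rmse

    def test_environmental_label_matches_ground_truth(self):
        dv, _, truth = generate_compound(SyntheticConfig(n_genes=800, seed=15), "C", 15)
        res = multi_restart_deconvolute(dv, NMFConfig(k=2, restarts=10, repeats=3, seed=15))
        r_env = np.corrcoef(res.w_env, truth.W_env_true)[0, 1]
        r_cross = np.corrcoef(res.w_drug, truth.W_env_true)[0, 1]
        assert r_env > r_cross

    def test_noise_free_pipeline_recovers_weights(self):
        """Noise-free separable rank-2 data recovers the true weights.

        Exact recovery requires the identifiable regime: marker genes
        exclusive to each component plus pure samples pin the ray
        directions. Pure-sample weights are then exact; interior weights
        retain a small distortion because the ALS component scales are a
        flat direction of the loss and the per-column normalization of H
        does not remove that freedom (see docs/methods.md).
        """
        rng = np.random.default_rng(16)
        W_true = rng.lognormal(0, 0.5, size=(300, 2))
        W_true[:15, 1] = 0.0  # markers of the first component
        W_true[15:30, 0] = 0.0  # markers of the second
        h = np.array([0.0, 1.0, 0.25, 0.5, 0.75, 0.9])
        H_true = np.vstack([1 - h, h])
        V = W_true @ H_true
        ds = make_compound_dataset(V, W_true[:, :1])
        res = multi_restart_deconvolute(
            ds, NMFConfig(k=2, restarts=30, repeats=5, seed=16, max_iter=2000, tol=1e-14)
        )
        ei = res.component_index(ENVIRONMENTAL)
        H_est = res.H_star[[ei, 1 - ei], :]
        assert np.abs(H_est[:, :2] - H_true[:, :2]).max() <= 1e-3  # pure samples
        assert np.abs(H_est - H_true).max() <= 0.03  # scale-drift bound


class TestPostModifiedNMFEstimator:
    def test_fit_transform_shapes_and_invariants(self):
        V, _, _ = random_rank2(m=120, n=8, seed=17, noise=0.05)
        est = PostModifiedNMF(n_components=2, restarts=4, repeats=2, random_state=0)
        weights = est.fit_transform(V.T)
        assert weights.shape == (8, 2)
        np.testing.assert_allclose(weights.sum(axis=1), 1.0, atol=1e-9)
        assert est.components_.shape == (2, 120)
        assert est.components_.min() >= 0
        assert est.reconstruction_rmse_ >= 0

    def test_transform_close_to_training_weights(self):
        V, _, _ = random_rank2(m=120, n=8, seed=18, noise=0.01)
        est = PostModifiedNMF(n_components=2, restarts=4, repeats=2, random_state=1)
        weights = est.fit_transform(V.T)
        np.testing.assert_allclose(est.transform(V.T), weights, atol=0.05)

    def test_clone_and_params(self):
        est = PostModifiedNMF(n_components=2, restarts=7, random_state=5)
        cl = clone(est)
        assert cl.get_params()["restarts"] == 7
        assert cl.get_params()["random_state"] == 5
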