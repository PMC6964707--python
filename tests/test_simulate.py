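import numpy as np
import pytest

from toxdeconv.core_data import System
from toxdeconv.deconvolution import NMFConfig, multi_restart_deconvolute
from toxdeconv.errors import DataError
from toxdeconv.simulate import (
    RegressionParams,
    average_invitro,
    build_modified_W,
    concordance_metrics,
    fit_scale_regression,
    simulate_compound,
    simulate_invivo,
)
from toxdeconv.synthetic import SyntheticConfig, generate_compound

from conftest import make_compound_dataset


class TestAverageInvitro:
    def test_identical_replicates(self):
        prof = np.array([1.0, 2.0, 3.0])
        ds = make_compound_dataset(
            np.column_stack([prof, prof]), prof[:, None], system=System.IN_VITRO
        )
        np.testing.assert_array_equal(average_invitro(ds), prof)

    def test_arithmetic_mean(self):
        ds = make_compound_dataset(
            np.array([[1.0, 3.0]]), np.array([[1.0]]), system=System.IN_VITRO
        )
        np.testing.assert_array_equal(average_invitro(ds), [2.0])

    def test_gene_mismatch_directs_to_intersect(self):
        ds = make_compound_dataset(np.ones((2, 1)), np.ones((2, 1)))
        with pytest.raises(DataError, match="intersect_genes"):
            average_invitro(ds, gene_ids=["other1", "other2"])


class TestScaleRegression:
    def test_identity(self):
        x = np.random.default_rng(0).random(100)
        reg = fit_scale_regression(x, x)
        assert reg.slope == pytest.approx(1.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.r_squared == pytest.approx(1.0)

    def test_exact_affine_construction(self):
        x = np.random.default_rng(1).lognormal(0, 0.5, 500)
        reg = fit_scale_regression(0.86 * x + 0.31, x)
        assert reg.slope == pytest.approx(0.86, abs=1e-6)
        assert reg.intercept == pytest.approx(0.31, abs=1e-6)

    def test_noise_shrinks_r_squared_monotonically(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0, 0.5, 2000)
        r2 = []
        for sd in (0.0, 0.3, 1.0, 3.0):
            y = 0.9 * x + 0.2 + rng.normal(0, sd, x.size)
            r2.append(fit_scale_regression(y, x).r_squared)
        assert r2 == sorted(r2, reverse=True)

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError, match="zero variance"):
            fit_scale_regression(np.arange(5.0), np.ones(5))


class TestBuildModifiedW:
    def test_replacement_identity(self):
        rng = np.random.default_rng(3)
        w_env, w_drug = rng.random(20), rng.random(20)
        W = build_modified_W(w_env, w_drug)
        np.testing.assert_array_equal(W, np.column_stack([w_env, w_drug]))

    def test_identity_regression_equals_no_regression(self):
        rng = np.random.default_rng(4)
        w_env, x = rng.random(20), rng.random(20)
        W1 = build_modified_W(w_env, x, None)
        W2 = build_modified_W(w_env, x, RegressionParams(1.0, 0.0, 1.0))
        np.testing.assert_array_equal(W1, W2)

    def test_affine_applied_elementwise_and_env_position(self):
        rng = np.random.default_rng(5)
        w_env, x = rng.random(20), rng.random(20)
        reg = RegressionParams(0.86, 0.31, 0.9)
        W = build_modified_W(w_env, x, reg, env_index=1)
        np.testing.assert_allclose(W[:, 0], 0.86 * x + 0.31)
        np.testing.assert_array_equal(W[:, 1], w_env)

    def test_negative_after_correction_clamped(self):
        W = build_modified_W(np.ones(3), np.array([0.1, 1.0, 2.0]),
                             RegressionParams(1.0, -0.5, 0.5))
        assert W.min() >= 0
        assert W[0, 1] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError, match="equal-length"):
            build_modified_W(np.ones(3), np.ones(4))


class TestSimulateInvivo:
    def test_identity_replacement_reproduces_reconstruction(self):
        rng = np.random.default_rng(6)
        W = rng.random((30, 2))
        H = rng.dirichlet([1, 1], size=5).T
        np.testing.assert_array_equal(simulate_invivo(W, H), W @ H)

    def test_one_hot_columns_pick_components(self):
        rng = np.random.default_rng(7)
        W = rng.random((10, 2))
        H = np.array([[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_array_equal(simulate_invivo(W, H), W)

    def test_matches_naive_triple_loop_oracle(self):
        rng = np.random.default_rng(8)
        W = rng.random((7, 2))
        H = rng.random((2, 4))
        out = simulate_invivo(W, H)
        naive = np.zeros((7, 4))
        for i in range(7):
            for j in range(4):
                for l in range(2):
                    naive[i, j] += W[i, l] * H[l, j]
        np.testing.assert_allclose(out, naive, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError, match="non-conformable"):
            simulate_invivo(np.ones((5, 3)), np.ones((2, 4)))


class TestConcordanceMetrics:
    def test_identical_vectors(self):
        x = np.random.default_rng(9).random(50)
        r2, rmse = concordance_metrics(x, x)
        assert r2 == pytest.approx(1.0)
        assert rmse == 0.0

    def test_constant_offset(self):
        x = np.random.default_rng(10).random(50)
        r2, rmse = concordance_metrics(x, x + 1.0)
        assert r2 == pytest.approx(1.0)
        assert rmse == pytest.approx(1.0)

    def test_independent_vectors_near_zero_r2(self):
        rng = np.random.default_rng(11)
        r2s = [concordance_metrics(rng.random(5000), rng.random(5000))[0] for _ in range(10)]
        assert np.mean(r2s) < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError, match="zero variance"):
            concordance_metrics(np.ones(5), np.arange(5.0))


class TestEndToEnd:
    def test_self_replacement_identity(self):
        """Swapping the drug column for itself reproduces W* . H* bitwise."""
        dv, _, _ = generate_compound(SyntheticConfig(n_genes=300, seed=20), "C", 20)
        res = multi_restart_deconvolute(dv, NMFConfig(k=2, restarts=5, repeats=2, seed=20))
        env_idx = res.component_index("environmental")
        W_mod = build_modified_W(res.w_env, res.w_drug, None, env_index=env_idx)
        np.testing.assert_array_equal(W_mod, res.W_star)
        np.testing.assert_array_equal(simulate_invivo(W_mod, res.H_star), res.W_star @ res.H_star)

    def test_simulate_compound_bundle_consistency(self):
        dv, dt, _ = generate_compound(SyntheticConfig(n_genes=300, seed=21), "C", 21)
        res = multi_restart_deconvolute(dv, NMFConfig(k=2, restarts=5, repeats=2, seed=21))
        bundle = simulate_compound(res, dt, regress=True)
        np.testing.assert_array_equal(
            bundle.V_simulated, bundle.W_modified @ bundle.H_invivo_star
        )
        assert bundle.V_simulated.min() >= 0
        assert bundle.regression is not None
        env_idx = res.component_index("environmental")
        np.testing.assert_array_equal(bundle.W_modified[:, env_idx], res.w_env)
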