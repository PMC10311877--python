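"""Training objective components and the fitting loop."""

import numpy as np
import pytest

from qrer import (CovariateMatrix, TrainingConfig, ks_statistic, mmd_loss,
                  rbf_kernel, regularizer_balance, regularizer_dispersion,
                  total_loss, train_qrer, update_bandwidth)
from qrer.network import Adam, build_generator, identity_init_loss
from qrer.reweight import delta_batch, sample_dirichlet_batch
from qrer.training import (_mmd_value_and_grads, median_heuristic_gamma,
                           stopping_metric)


def mmd_double_loop(dw, dt, gamma):
    """O(B^2) brute-force transcription of the V-statistic MMD."""
    B = len(dw)
    k = lambda x, y: np.exp(-gamma * np.sum((x - y) ** 2))
    s = 0.0
    for i in range(B):
        for j in range(B):
            s += k(dw[i], dw[j]) + k(dt[i], dt[j]) - 2 * k(dw[i], dt[j])
    return np.sqrt(max(s / B**2, 0.0))


@pytest.fixture
def tiny_cov(rng):
    X = rng.standard_normal((24, 3)) + np.array([0.4, 0.0, -0.2])
    T = np.array([1] * 10 + [0] * 14)
    return CovariateMatrix.from_arrays(X, T)


class TestRbfKernel:
    def test_identical_points(self):
        assert rbf_kernel([1.0, 2.0], [1.0, 2.0], 3.0) == 1.0

    def test_unit_distance(self):
        assert rbf_kernel([0.0], [1.0], 1.0) == pytest.approx(np.exp(-1))

    def test_small_gamma_limit(self, rng):
        x, y = rng.standard_normal(4), rng.standard_normal(4)
        assert rbf_kernel(x, y, 1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            rbf_kernel([0.0], [1.0], 0.0)


class TestMmdLoss:
    def test_zero_on_identical_samples(self, rng):
        d = rng.standard_normal((16, 3))
        assert mmd_loss(d, d.copy(), 0.7) == pytest.approx(0.0, abs=1e-7)

    def test_single_pair_hand_value(self):
        # B=1: sqrt(1 + 1 - 2 e^{-1}) ~ 1.124385
        assert mmd_loss([[0.0]], [[1.0]], 1.0) == pytest.approx(1.124385,
                                                               abs=1e-6)

    @pytest.mark.parametrize("B,d", [(3, 1), (16, 2), (64, 5)])
    def test_double_loop_oracle(self, rng, B, d):
        dw = rng.standard_normal((B, d))
        dt = rng.standard_normal((B, d)) + 0.3
        assert mmd_loss(dw, dt, 0.5) == pytest.approx(
            mmd_double_loop(dw, dt, 0.5), abs=1e-10)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            mmd_loss(rng.standard_normal((4, 2)),
                     rng.standard_normal((5, 2)), 1.0)

    def test_gradients_match_finite_differences(self, rng):
        dw = rng.standard_normal((6, 3))
        dt = rng.standard_normal((6, 3)) + 0.5
        gamma = 0.8
        _, gW, ggamma = _mmd_value_and_grads(dw, dt, gamma)
        eps = 1e-6
        i, j = 2, 1
        up, dn = dw.copy(), dw.copy()
        up[i, j] += eps
        dn[i, j] -= eps
        fd = (mmd_loss(up, dt, gamma) - mmd_loss(dn, dt, gamma)) / (2 * eps)
        assert gW[i, j] == pytest.approx(fd, rel=1e-3, abs=1e-8)
        fd_g = (mmd_loss(dw, dt, gamma + eps)
                - mmd_loss(dw, dt, gamma - eps)) / (2 * eps)
        assert ggamma == pytest.approx(fd_g, rel=1e-5)


class TestRegularizers:
    def test_balance_hand_value(self, ladder_cov):
        # uniform weights: arm means 1.5 and 3.5 vs pooled mean 2.5 -> 2.0
        r1 = regularizer_balance(ladder_cov, np.array([[0.5, 0.5]]),
                                 np.array([[0.5, 0.5]]))
        assert r1 == pytest.approx(2.0)

    def test_balance_zero_iff_arm_means_equal_pooled(self):
        # d=1: put weight w on x=1 s.t. w*1 + (1-w)*4 = pooled mean
        X = np.array([[1.0], [4.0], [2.0], [3.0]])
        cov = CovariateMatrix.from_arrays(X, [1, 1, 0, 0])
        xbar = 2.5
        w1 = np.array([[(4 - xbar) / 3, 1 - (4 - xbar) / 3]])
        w0 = np.array([[0.5, 0.5]])        # 0.5*2+0.5*3 = 2.5 = xbar
        assert regularizer_balance(cov, w1, w0) == pytest.approx(0.0, abs=1e-12)
        assert regularizer_balance(cov, np.array([[1.0, 0.0]]), w0) > 0

    def test_dispersion_hand_value(self):
        r2 = regularizer_dispersion(np.array([[1.0, 0.0]]),
                                    np.array([[0.5, 0.5]]))
        assert r2 == pytest.approx(0.5)

    def test_dispersion_zero_iff_uniform(self, rng):
        uni1 = np.full((3, 4), 0.25)
        uni0 = np.full((3, 5), 0.2)
        assert regularizer_dispersion(uni1, uni0) == 0.0
        w1, w0 = sample_dirichlet_batch(3, 4, 5, rng)
        assert regularizer_dispersion(w1, w0) > 0

    def test_total_loss_composes(self, tiny_cov, rng):
        w1, w0 = sample_dirichlet_batch(8, tiny_cov.N1, tiny_cov.N0, rng)
        dT = rng.standard_normal((8, 3)) * 0.1
        dW = delta_batch(tiny_cov, w1, w0)
        expected = (mmd_loss(dW, dT, 2.0)
                    + 0.5 * regularizer_balance(tiny_cov, w1, w0)
                    + 1.5 * regularizer_dispersion(w1, w0))
        got = total_loss(tiny_cov, w1, w0, dT, 2.0, lambda1=0.5, lambda2=1.5)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_lambda_zero_reduces_to_mmd(self, tiny_cov, rng):
        w1, w0 = sample_dirichlet_batch(8, tiny_cov.N1, tiny_cov.N0, rng)
        dT = rng.standard_normal((8, 3)) * 0.1
        dW = delta_batch(tiny_cov, w1, w0)
        assert total_loss(tiny_cov, w1, w0, dT, 2.0, 0.0, 0.0) == \
            pytest.approx(mmd_loss(dW, dT, 2.0))


class TestBandwidth:
    def test_identical_batches_leave_gamma_unchanged(self, rng):
        d = rng.standard_normal((8, 2))
        opt = Adam([(1,)])
        lg = update_bandwidth(np.log(2.0), opt, d, d.copy())
        assert lg == pytest.approx(np.log(2.0))

    def test_separated_singletons_increase_gamma(self):
        # L(gamma) = sqrt(2 - 2 e^{-gamma}) is increasing in gamma
        opt = Adam([(1,)])
        lg = update_bandwidth(np.log(1.0), opt, np.array([[0.0]]),
                              np.array([[1.0]]))
        assert lg > np.log(1.0)

    def test_gamma_stays_positive(self, rng):
        lg = float(np.log(0.5))
        opt = Adam([(1,)])
        dw = rng.standard_normal((16, 2))
        dt = rng.standard_normal((16, 2))
        for _ in range(200):
            lg = update_bandwidth(lg, opt, dw, dt)
        assert np.isfinite(lg) and np.exp(lg) > 0

    def test_median_heuristic_positive(self, rng):
        assert median_heuristic_gamma(rng.standard_normal((32, 4))) > 0


class TestKsStatistic:
    def test_identical_samples(self):
        assert ks_statistic([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports(self):
        assert ks_statistic([1, 2], [3, 4]) == 1.0

    def test_interleaved(self):
        assert ks_statistic([1, 3], [2, 4]) == 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1.0])


def _tiny_config(p_a=0.5, **kw):
    defaults = dict(p_a=p_a, B=64, B_init=128, B_stop=128, B_loss=256,
                    N_init=60, N_train=150, N_stop=2, eval_every=50)
    defaults.update(kw)
    return TrainingConfig(**defaults)


class TestTrainQrer:
    def test_returns_best_metric_not_worse_than_initial(self, tiny_cov):
        model, trace = train_qrer(tiny_cov, _tiny_config(),
                                  np.random.default_rng(5))
        assert trace.best_metric <= trace.initial_metric
        assert model.gamma > 0
        assert 0 <= trace.best_metric <= 1
        assert all(0 <= k <= 1 for k in trace.ks_metric)

    def test_bit_for_bit_reproducible(self, tiny_cov):
        m1, t1 = train_qrer(tiny_cov, _tiny_config(), np.random.default_rng(9))
        m2, t2 = train_qrer(tiny_cov, _tiny_config(), np.random.default_rng(9))
        for a, b in zip(m1.params, m2.params):
            assert np.array_equal(a, b)
        assert t1.mmd == t2.mmd and t1.ks_metric == t2.ks_metric

    def test_stopping_metric_deterministic_with_fixed_masks(self, tiny_cov,
                                                            rng):
        model = build_generator(tiny_cov.N1, tiny_cov.N0, rng, hidden=32)
        w1, w0 = sample_dirichlet_batch(64, tiny_cov.N1, tiny_cov.N0, rng)
        D = rng.chisquare(3, size=64)
        a = stopping_metric(model, tiny_cov, w1.astype(np.float32),
                            w0.astype(np.float32), D, dropout_seed=11)
        b = stopping_metric(model, tiny_cov, w1.astype(np.float32),
                            w0.astype(np.float32), D, dropout_seed=11)
        assert a == b

    def test_smaller_pa_gives_more_concentrated_weighted_distances(self,
                                                                   tiny_cov):
        """Training against a stricter template shrinks weighted distances."""
        from qrer.network import generate_weight_arrays
        from qrer.reweight import weighted_mahalanobis_batch
        means = {}
        for p_a in (0.1, 1.0):
            model, _ = train_qrer(tiny_cov, _tiny_config(p_a=p_a, N_train=400),
                                  np.random.default_rng(31))
            w1, w0 = generate_weight_arrays(model, 400,
                                            np.random.default_rng(7))
            means[p_a] = weighted_mahalanobis_batch(tiny_cov, w1, w0).mean()
        assert means[0.1] < means[1.0]

    def test_large_lambda2_pulls_weights_toward_uniform(self, tiny_cov, rng):
        """R2 dominance: more penalty, less dispersion, estimator closer to
        the raw mean difference."""
        from qrer import generate_weights, tau_ensemble
        from qrer.network import generate_weight_arrays
        from qrer.training import regularizer_dispersion
        Y = tiny_cov.X[:, 0] + tiny_cov.T_obs + rng.standard_normal(tiny_cov.N)
        raw = Y[: tiny_cov.N1].mean() - Y[tiny_cov.N1:].mean()
        disp, gap = {}, {}
        for lam2 in (0.2, 200.0):
            cfg = _tiny_config(lambda2=lam2, N_train=400)
            model, _ = train_qrer(tiny_cov, cfg, np.random.default_rng(13))
            w1, w0 = generate_weight_arrays(model, 200,
                                            np.random.default_rng(7))
            disp[lam2] = regularizer_dispersion(w1, w0)
            ws = generate_weights(model, 200, np.random.default_rng(7))
            gap[lam2] = abs(tau_ensemble(ws, tiny_cov.T_obs, Y) - raw)
        assert disp[200.0] < disp[0.2]
        assert gap[200.0] < gap[0.2]

    def test_backward_matches_finite_differences(self, rng):
        """End-to-end network gradient check through the identity loss."""
        model = build_generator(3, 4, rng, hidden=8)
        model.dropout_rate = 0.0
        w1, w0 = sample_dirichlet_batch(5, 3, 4, rng)
        w1f, w0f = w1.astype(np.float32), w0.astype(np.float32)
        loss, (cache, o1, o0, l1, l0, B) = identity_init_loss(
            model, w1f, w0f, train=True, rng=rng)
        grads = model.backward(cache, (2.0 / B) * l1 / o1, (2.0 / B) * l0 / o0)
        for p, g in zip(model.params, grads):
            idx = tuple(rng.integers(0, s) for s in p.shape)
            eps = 1e-3        # small enough to avoid ReLU kink crossings
            orig = p[idx]
            p[idx] = orig + eps
            up, _ = identity_init_loss(model, w1f, w0f)
            p[idx] = orig - eps
            dn, _ = identity_init_loss(model, w1f, w0f)
            p[idx] = orig
            assert float(g[idx]) == pytest.approx((up - dn) / (2 * eps),
                                                  rel=2e-2, abs=2e-3)
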