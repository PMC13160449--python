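"""Hypergraph contrastive encoder: propagation algebra, loss closed forms,
gradient correctness and training contracts."""

import numpy as np
import pytest
import scipy.sparse as sp

from hypermatch.encoder import (
    EncoderConfig,
    _loss_and_grad,
    contrastive_loss,
    encode,
    global_propagate,
    local_propagate,
    train_encoder,
)


def brute_force_contrastive(local_layers, global_layers, tau):
    """Double-loop InfoNCE, the oracle for the vectorized implementation."""

    def cos(a, b):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            return 0.0
        return float(a @ b / (na * nb))

    total = 0.0
    for u, v in zip(local_layers, global_layers):
        n = u.shape[0]
        for i in range(n):
            num = np.exp(cos(u[i], v[i]) / tau)
            den = sum(np.exp(cos(u[i], v[j]) / tau) for j in range(n))
            total -= np.log(num / den)
    return total


class TestLocalPropagate:
    def test_identity_operator(self, rng):
        x = rng.normal(size=(5, 3))
        np.testing.assert_allclose(local_propagate(sp.identity(5), x), x)

    def test_averaging_operator(self):
        op = np.full((2, 2), 0.5)
        prev = np.array([[2.0, 0.0], [0.0, 4.0]])
        out = local_propagate(op, prev)
        np.testing.assert_allclose(out, np.array([[1.0, 2.0], [1.0, 2.0]]))

    def test_row_stochastic_preserves_constant_rows(self, rng):
        a = rng.random((6, 6))
        op = a / a.sum(axis=1, keepdims=True)
        prev = np.tile(rng.normal(size=3), (6, 1))
        np.testing.assert_allclose(local_propagate(op, prev), prev, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            local_propagate(sp.identity(4), rng.normal(size=(5, 2)))


class TestGlobalPropagate:
    def test_zero_incidence(self, rng):
        base = rng.normal(size=(4, 3))
        out = global_propagate(base, np.zeros((3, 2)), rng.normal(size=(4, 3)))
        assert not out.any()

    def test_single_cell_scalar_expansion(self, rng):
        base = rng.normal(size=(1, 3))
        w = rng.normal(size=(3, 2))
        prev = rng.normal(size=(1, 3))
        h = base @ w
        np.testing.assert_allclose(global_propagate(base, w, prev),
                                   (h @ h.T) * prev)

    def test_identity_incidence(self):
        base = np.eye(3)
        prev = np.arange(9, dtype=float).reshape(3, 3)
        np.testing.assert_allclose(global_propagate(base, np.eye(3), prev), prev)

    def test_factored_equals_explicit_product(self, rng):
        for _ in range(5):
            base = rng.normal(size=(6, 4))
            w = rng.normal(size=(4, 3))
            prev = rng.normal(size=(6, 4))
            h = base @ w
            np.testing.assert_allclose(global_propagate(base, w, prev),
                                       (h @ h.T) @ prev, atol=1e-10)


class TestContrastiveLoss:
    def test_single_cell_zero(self, rng):
        u = [rng.normal(size=(1, 4))]
        assert contrastive_loss(u, [rng.normal(size=(1, 4))], 0.5) == pytest.approx(0.0)

    def test_uniform_similarity_closed_form(self):
        layers = [np.ones((4, 3))] * 2
        assert contrastive_loss(layers, layers, 0.5) == pytest.approx(8 * np.log(4), abs=1e-9)

    def test_orthonormal_hand_case(self):
        e = [np.eye(2)]
        assert contrastive_loss(e, e, 1.0) == pytest.approx(2 * np.log(1 + np.exp(-1)), abs=1e-9)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            u = [rng.normal(size=(5, 3)) for _ in range(2)]
            v = [rng.normal(size=(5, 3)) for _ in range(2)]
            assert contrastive_loss(u, v, 0.7) == pytest.approx(
                brute_force_contrastive(u, v, 0.7), abs=1e-10)

    def test_nonnegative_with_zero_rows(self, rng):
        u = [np.vstack([np.zeros(3), rng.normal(size=(3, 3))])]
        v = [np.vstack([rng.normal(size=(2, 3)), np.zeros((2, 3))])]
        assert contrastive_loss(u, v, 0.5) >= 0

    def test_invalid_tau(self, rng):
        with pytest.raises(ValueError):
            contrastive_loss([rng.normal(size=(2, 2))], [rng.normal(size=(2, 2))], 0.0)


class TestGradient:
    def test_analytic_matches_finite_differences(self, rng):
        n, d, K = 6, 4, 3
        base = rng.normal(size=(n, d))
        a = rng.random((n, n)) * 0.5
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        op = sp.csr_matrix((a + np.eye(n)) / (a + np.eye(n)).sum(1, keepdims=True))
        w = rng.normal(size=(d, K)) * 0.3
        cfg = EncoderConfig(L=2, K=K, tau=0.6, lam=0.01, epochs=1, seed=0)
        _, g = _loss_and_grad(base, op, w, cfg, np.random.default_rng(0))
        eps = 1e-6
        for _ in range(10):
            i, j = rng.integers(d), rng.integers(K)
            wp, wm = w.copy(), w.copy()
            wp[i, j] += eps
            wm[i, j] -= eps
            lp, _ = _loss_and_grad(base, op, wp, cfg, np.random.default_rng(0))
            lm, _ = _loss_and_grad(base, op, wm, cfg, np.random.default_rng(0))
            assert g[i, j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5, rel=1e-4)


class TestTraining:
    def _setup(self, rng, n=30, d=5):
        base = rng.normal(size=(n, d))
        a = rng.random((n, n)) * (rng.random((n, n)) > 0.7)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        a_hat = a + np.eye(n)
        dinv = np.diag(a_hat.sum(1) ** -0.5)
        return base, sp.csr_matrix(dinv @ a_hat @ dinv)

    def test_epochs_zero_is_seeded_forward_pass(self, rng):
        base, op = self._setup(rng)
        st = train_encoder(base, op, EncoderConfig(epochs=0, seed=3))
        assert st.loss_trace == []
        assert np.all(np.isfinite(st.fused))

    def test_fusion_identity(self, rng):
        base, op = self._setup(rng)
        st = train_encoder(base, op, EncoderConfig(epochs=3, seed=3))
        total = sum(e + g for e, g in zip(st.local_layers, st.global_layers))
        np.testing.assert_allclose(st.fused, total, atol=1e-12)

    def test_determinism(self, rng):
        base, op = self._setup(rng)
        cfg = EncoderConfig(epochs=5, seed=11)
        a = train_encoder(base, op, cfg)
        b = train_encoder(base, op, cfg)
        np.testing.assert_array_equal(a.fused, b.fused)

    def test_huge_weight_decay_shrinks_w(self, rng):
        base, op = self._setup(rng)
        init = train_encoder(base, op, EncoderConfig(epochs=0, seed=5)).W
        trained = train_encoder(base, op, EncoderConfig(epochs=100, lam=1e6, seed=5)).W
        assert np.linalg.norm(trained) < np.linalg.norm(init)

    def test_loss_decreases_most_seeds(self, rng):
        base, op = self._setup(rng, n=40)
        wins = 0
        for seed in range(5):
            st = train_encoder(base, op, EncoderConfig(epochs=60, seed=seed))
            wins += st.loss_trace[-1] <= st.loss_trace[0]
        assert wins >= 4

    def test_encode_shape_and_k_sensitivity(self, rng):
        base, op = self._setup(rng)
        e1 = encode(base, op, EncoderConfig(epochs=2, K=4, seed=9))
        e2 = encode(base, op, EncoderConfig(epochs=2, K=8, seed=9))
        assert e1.shape == base.shape == e2.shape
        assert not np.allclose(e1, e2)

    def test_subsampled_negatives_run(self, rng):
        base, op = self._setup(rng, n=25)
        st = train_encoder(base, op, EncoderConfig(epochs=3, seed=1,
                                                   negatives_per_anchor=5))
        assert np.all(np.isfinite(st.fused))
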