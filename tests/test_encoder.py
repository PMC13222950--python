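"""Polarized linear attention, PSEN, MAEM and the HSATE block.

The PLA oracle here evaluates the polarity decomposition term by term
with explicit Python loops — no shared code with the vectorized path.
"""

import numpy as np
import pytest

from dsadet import nn
from dsadet.encoder import (
    AIFI,
    HSATEBlock,
    MAEM,
    MAEMOp,
    MAEMParams,
    PLAParams,
    PolarizedLinearAttention,
    PSEN,
    TokenSequence,
    kernel_phi,
    pla_attention,
    softmax_attention,
)
from dsadet.nn.tensor import Tensor, counting_macs


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def softmax_attention_loops(Q, K, V, d_k):
    """Explicit double loop over token pairs."""
    N, d = Q.shape
    out = np.zeros_like(V)
    for i in range(N):
        logits = np.array([Q[i] @ K[j] / np.sqrt(d_k) for j in range(N)])
        w = np.exp(logits - logits.max())
        w /= w.sum()
        for j in range(N):
            out[i] += w[j] * V[j]
    return out


def pla_loops(Q, K, V, alpha, eps=1e-6):
    """Term-by-term evaluation of both polarity terms with loops."""
    N, d = Q.shape

    def phi(x):
        return np.maximum(x, 0.0) ** alpha

    out = np.zeros_like(V)
    for sign in (+1.0, -1.0):
        kv = np.zeros((d, d))
        kmass = np.zeros(d)
        for j in range(N):
            pk = phi(sign * K[j])
            kv += np.outer(pk, V[j])
            kmass += pk
        kv /= N
        kmass /= N
        for i in range(N):
            pq = phi(sign * Q[i])
            out[i] += sign * (pq @ kv) / (pq @ kmass + eps)
    return out


# ---------------------------------------------------------------------------
# kernel and attention primitives
# ---------------------------------------------------------------------------


class TestKernelPhi:
    def test_alpha_one_is_rectifier(self):
        assert np.allclose(kernel_phi(np.array([-1.0, 2.0]), 1.0), [0.0, 2.0])

    def test_alpha_two_squares_positive_part(self):
        assert np.allclose(kernel_phi(np.array([3.0, -3.0]), 2.0), [9.0, 0.0])

    def test_zero_maps_to_zero_and_output_nonnegative(self, rng):
        assert kernel_phi(np.zeros(3), 1.7).max() == 0.0
        x = rng.standard_normal(100)
        assert kernel_phi(x, 0.8).min() >= 0.0

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            kernel_phi(np.ones(2), 0.0)


class TestSoftmaxAttention:
    def test_single_token_returns_value(self):
        out = softmax_attention(
            Tensor(np.array([[1.0]])), Tensor(np.array([[1.0]])),
            Tensor(np.array([[7.0]])), 1
        )
        assert np.allclose(out.data, [[7.0]])

    def test_identical_keys_average_values(self, rng):
        N, d = 6, 4
        K = np.tile(rng.standard_normal(d), (N, 1))
        Q = rng.standard_normal((N, d))
        V = rng.standard_normal((N, d))
        out = softmax_attention(Tensor(Q), Tensor(K), Tensor(V), d)
        assert np.allclose(out.data, np.tile(V.mean(axis=0), (N, 1)), atol=1e-6)

    def test_matches_double_loop_oracle(self, rng):
        Q, K, V = (rng.standard_normal((5, 4)) for _ in range(3))
        out = softmax_attention(Tensor(Q), Tensor(K), Tensor(V), 4)
        assert np.allclose(out.data, softmax_attention_loops(Q, K, V, 4), atol=1e-10)

    def test_attention_rows_sum_to_one(self, rng):
        from dsadet.nn import functional as F

        scores = Tensor(rng.standard_normal((3, 8, 8)))
        rows = F.softmax(scores, axis=-1).data.sum(axis=-1)
        assert np.abs(rows - 1.0).max() < 1e-6

    def test_rejects_bad_dk(self):
        with pytest.raises(ValueError):
            softmax_attention(Tensor(np.ones((2, 2))), Tensor(np.ones((2, 2))),
                              Tensor(np.ones((2, 2))), 0)


class TestPLA:
    def test_zero_inputs_give_zero(self):
        z = Tensor(np.zeros((4, 3)))
        out = pla_attention(z, z, z, PLAParams(alpha=1.0, head_dim=3))
        assert np.allclose(out.data, 0.0)

    def test_key_value_permutation_invariance(self, rng):
        Q = rng.standard_normal((6, 3))
        K = rng.standard_normal((6, 3))
        V = rng.standard_normal((6, 3))
        p = PLAParams(alpha=1.3, head_dim=3)
        out = pla_attention(Tensor(Q), Tensor(K), Tensor(V), p)
        perm = rng.permutation(6)
        out_p = pla_attention(Tensor(Q), Tensor(K[perm]), Tensor(V[perm]), p)
        assert np.allclose(out.data, out_p.data, atol=1e-6)

    def test_matches_loop_oracle(self, rng):
        Q = rng.standard_normal((6, 3))
        K = rng.standard_normal((6, 3))
        V = rng.standard_normal((6, 3))
        out = pla_attention(Tensor(Q), Tensor(K), Tensor(V),
                            PLAParams(alpha=1.0, head_dim=3))
        want = pla_loops(Q, K, V, 1.0)
        assert np.abs(out.data - want).max() < 1e-8

    def test_mac_growth_linear_vs_quadratic(self):
        """Doubling N doubles PLA cost but quadruples the softmax
        reference's dominant terms."""
        d = 8

        def pla_macs(N):
            x = Tensor(np.random.default_rng(0).standard_normal((N, d)))
            with counting_macs() as macs:
                pla_attention(x, x, x, PLAParams(alpha=1.0, head_dim=d))
            return macs[0]

        def soft_macs(N):
            x = Tensor(np.random.default_rng(0).standard_normal((N, d)))
            with counting_macs() as macs:
                softmax_attention(x, x, x, d)
            return macs[0]

        assert pla_macs(256) / pla_macs(128) == pytest.approx(2.0, rel=1e-6)
        assert soft_macs(256) / soft_macs(128) == pytest.approx(4.0, rel=0.01)


# ---------------------------------------------------------------------------
# PSEN / MAEM / HSATE
# ---------------------------------------------------------------------------


def _tokens(rng, B=1, H=8, W=8, C=16):
    data = Tensor(rng.standard_normal((B, H * W, C)).astype(np.float32))
    return TokenSequence(data, (H, W))


class TestPSEN:
    def test_shape_preserved(self, rng):
        psen = PSEN(16).eval()
        x = _tokens(rng)
        out = psen(x, x)
        assert out.data.shape == (1, 64, 16)

    def test_odd_grid_is_padded(self, rng):
        psen = PSEN(8).eval()
        x = TokenSequence(Tensor(rng.standard_normal((1, 35, 8)).astype(np.float32)), (5, 7))
        out = psen(x, x)
        assert out.data.shape == (1, 35, 8)

    def test_constant_plane_survives_pool_and_upsample(self):
        """AvgPool(s=2) then x2 nearest upsampling of a constant field
        returns the same constant plane."""
        from dsadet.nn import functional as F

        x = Tensor(np.full((1, 3, 6, 6), 4.25, dtype=np.float32))
        y = F.upsample_nearest2d(F.avg_pool2d(x, 2), 2)
        assert np.array_equal(y.data, x.data)


class TestMAEMOp:
    def test_identity_at_zero_weights(self, rng):
        op = MAEMOp(8)
        for p in op.parameters():
            p.data[:] = 0.0
        x = Tensor(rng.standard_normal((1, 8, 6, 6)).astype(np.float32))
        assert np.allclose(op(x).data, x.data)

    def test_delta_kernels_double_input(self, rng):
        """Conv1x1 = 0 and centred-delta depthwise kernels give
        X + (1/3)(3X) = 2X."""
        op = MAEMOp(4)
        for p in op.parameters():
            p.data[:] = 0.0
        for conv, k in ((op.dw3, 3), (op.dw5, 5), (op.dw7, 7)):
            conv.weight.data[:, 0, k // 2, k // 2] = 1.0
        x = Tensor(rng.standard_normal((1, 4, 5, 5)).astype(np.float32))
        assert np.allclose(op(x).data, 2 * x.data, atol=1e-6)

    def test_shape_preserved(self, rng):
        op = MAEMOp(32)
        x = Tensor(rng.standard_normal((1, 32, 20, 20)).astype(np.float32))
        assert op(x).shape == x.shape


class TestMAEM:
    def test_identity_when_gammas_and_biases_zero(self, rng):
        m = MAEM(8).eval()
        m.gamma.data[:] = 0.0
        m.gamma_x.data[:] = 0.0
        for p in (m.conv_in.bias, m.conv_out.bias, m.op.pre.bias,
                  m.op.dw3.bias, m.op.dw5.bias, m.op.dw7.bias):
            p.data[:] = 0.0
        x = _tokens(rng, C=8)
        assert np.allclose(m(x).data.data, x.data.data, atol=1e-7)

    def test_identity_when_terminal_projection_zero(self, rng):
        m = MAEM(8).eval()
        m.gamma.data[:] = 1.0
        m.gamma_x.data[:] = 0.0
        m.conv_out.weight.data[:] = 0.0
        m.conv_out.bias.data[:] = 0.0
        x = _tokens(rng, C=8)
        assert np.allclose(m(x).data.data, x.data.data, atol=1e-7)

    def test_eval_mode_deterministic(self, rng):
        m = MAEM(8, dropout=0.5).eval()
        x = _tokens(rng, C=8)
        assert np.array_equal(m(x).data.data, m(x).data.data)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            MAEMParams(kernel_sizes=(3, 5))
        with pytest.raises(ValueError):
            MAEMParams(dropout_rate=1.0)


class TestHSATEBlock:
    def test_shape_preserved(self, rng):
        blk = HSATEBlock(embed_dim=16, num_heads=4).eval()
        x = _tokens(rng, H=10, W=10, C=16)
        out = blk(x)
        assert out.data.shape == (1, 100, 16)
        assert np.all(np.isfinite(out.data.data))

    def test_alpha_is_learnable_and_clamped(self, rng):
        blk = HSATEBlock(embed_dim=16, num_heads=4, alpha_init=5.0)
        x = _tokens(rng, C=16)
        out = blk(x)
        out.data.sum().backward()
        assert blk.attn.alpha.grad is not None

    def test_linear_token_scaling_of_attention_macs(self, rng):
        """Total attention MACs are affine in token count: the second
        difference over N in {64,128,256} vanishes relative to scale —
        no N×N product is ever formed."""
        attn = PolarizedLinearAttention(16, 4).eval()

        def macs_at(n):
            x = Tensor(rng.standard_normal((1, n, 16)).astype(np.float32))
            with counting_macs() as macs:
                attn(x)
            return macs[0]

        m64, m128, m256 = macs_at(64), macs_at(128), macs_at(256)
        assert abs((m256 - m128) - 2 * (m128 - m64)) <= 1e-6 * m256

    def test_aifi_baseline_shape(self, rng):
        blk = AIFI(embed_dim=16, num_heads=4, ffn_dim=32).eval()
        x = _tokens(rng, C=16)
        assert blk(x).data.shape == x.data.shape
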