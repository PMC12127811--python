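"""Transformer and dual-attention branches against brute-force oracles."""

import numpy as np
import pytest

from gliotype.attention import (
    ChannelAttention3d,
    MultiHeadSelfAttention,
    PatchEmbed3d,
    RDABlock,
    RDATail,
    SpatialAttention3d,
    TransformerLayer,
    ViT3d,
)
from gliotype.config import ModelConfig
from gliotype.nn import Tensor
from gliotype.nn.functional import conv3d_forward


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# patch embedding
# ---------------------------------------------------------------------------

class TestPatchEmbed:
    def test_token_count_and_width(self, rng):
        pe = PatchEmbed3d(8, 32, grid=4, patch_size=1, rng=rng)
        z = pe(Tensor(rng.standard_normal((2, 8, 4, 4, 4))))
        assert z.shape == (2, 64, 32)

    def test_zero_input_zero_bias_yields_position_embeddings(self, rng):
        pe = PatchEmbed3d(4, 16, grid=3, patch_size=1, rng=rng)
        pe.proj.bias.data[:] = 0.0
        z = pe(Tensor(np.zeros((1, 4, 3, 3, 3))))
        np.testing.assert_allclose(z.data[0], pe.pos.data, atol=1e-12)

    def test_locality_of_the_conv_projection(self, rng):
        # changing one voxel only perturbs tokens within the 3^3 footprint
        pe = PatchEmbed3d(2, 8, grid=5, patch_size=1, rng=rng)
        x0 = rng.standard_normal((1, 2, 5, 5, 5))
        x1 = x0.copy()
        x1[0, 0, 2, 2, 2] += 1.0
        z0 = pe(Tensor(x0)).data[0]
        z1 = pe(Tensor(x1)).data[0]
        changed = np.where(np.abs(z1 - z0).max(axis=1) > 1e-12)[0]
        zz, yy, xx = np.unravel_index(changed, (5, 5, 5))
        assert np.all(np.abs(zz - 2) <= 1)
        assert np.all(np.abs(yy - 2) <= 1)
        assert np.all(np.abs(xx - 2) <= 1)


# ---------------------------------------------------------------------------
# self-attention
# ---------------------------------------------------------------------------

def brute_force_attention(z, wq, wk, wv, n_heads):
    """Loop evaluation of softmax(QK^T/sqrt(d))V with head concat."""
    T, e = z.shape
    d = e // n_heads
    q, k, v = z @ wq, z @ wk, z @ wv
    out = np.zeros((T, e))
    for h in range(n_heads):
        sl = slice(h * d, (h + 1) * d)
        qh, kh, vh = q[:, sl], k[:, sl], v[:, sl]
        for i in range(T):
            scores = np.array([qh[i] @ kh[j] / np.sqrt(d) for j in range(T)])
            w = np.exp(scores - scores.max())
            w = w / w.sum()
            out[i, sl] = sum(w[j] * vh[j] for j in range(T))
    return out


class TestSelfAttention:
    def test_matches_brute_force_oracle_small(self, rng):
        msa = MultiHeadSelfAttention(4, n_heads=2, rng=rng)
        for lin in (msa.wq, msa.wk, msa.wv):
            lin.bias.data[:] = 0.0
        msa.wo.weight.data = np.eye(4)  # identity output projection
        msa.wo.bias.data[:] = 0.0
        z = rng.standard_normal((3, 4))
        expected = brute_force_attention(
            z, msa.wq.weight.data, msa.wk.weight.data, msa.wv.weight.data, 2
        )
        got = msa(Tensor(z[None])).data[0]
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_attention_rows_sum_to_one(self, rng):
        msa = MultiHeadSelfAttention(8, n_heads=2, rng=rng)
        z = Tensor(rng.standard_normal((1, 5, 8)))
        q = msa._split(msa.wq(z) * (1.0 / np.sqrt(msa.d).item()), 1, 5)
        k = msa._split(msa.wk(z), 1, 5)
        attn = (q @ k.transpose(0, 1, 3, 2)).softmax(axis=-1)
        np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-12)

    def test_identical_tokens_produce_identical_outputs(self, rng):
        msa = MultiHeadSelfAttention(6, n_heads=3, rng=rng)
        token = rng.standard_normal(6)
        z = Tensor(np.tile(token, (1, 7, 1)))
        out = msa(z).data[0]
        np.testing.assert_allclose(out, np.tile(out[0], (7, 1)), atol=1e-10)

    def test_permutation_equivariance(self, rng):
        msa = MultiHeadSelfAttention(8, n_heads=2, rng=rng)
        z = rng.standard_normal((1, 6, 8))
        perm = rng.permutation(6)
        out = msa(Tensor(z)).data[0]
        out_perm = msa(Tensor(z[:, perm])).data[0]
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)


class TestTransformerLayer:
    def test_zero_weight_subblocks_pass_through(self, rng):
        layer = TransformerLayer(8, 2, 4, rng)
        for name, p in layer.named_parameters():
            if "gamma" not in name:
                p.data = np.zeros_like(p.data)
        z = Tensor(rng.standard_normal((1, 5, 8)))
        np.testing.assert_array_equal(layer(z).data, z.data)

    def test_stack_preserves_shape_and_is_finite(self, rng):
        cfg = ModelConfig.scaled(0.125)
        vit = ViT3d(cfg, rng)
        c, f = cfg.path_channels, cfg.feature_size
        z = vit(Tensor(rng.standard_normal((2, c, f, f, f))))
        assert z.shape == (2, f**3, cfg.embed_dim)
        assert np.all(np.isfinite(z.data))
        assert len(vit.layers) == 4


# ---------------------------------------------------------------------------
# channel attention
# ---------------------------------------------------------------------------

class TestChannelAttention:
    def test_constant_channels_make_avg_equal_max(self, rng):
        ca = ChannelAttention3d(3, reduction=1, rng=rng)
        m = np.zeros((1, 3, 2, 2, 2))
        m[0] = np.array([1.0, -2.0, 0.5])[:, None, None, None]
        gate = ca.gate(Tensor(m)).data[0, :, 0, 0, 0]
        # AvgPool == MaxPool == c, so gate = sigmoid(2 * MLP(c))
        c = np.array([1.0, -2.0, 0.5])
        mlp = lambda v: ca.fc2.weight.data.T @ np.maximum(
            ca.fc1.weight.data.T @ v + ca.fc1.bias.data, 0) + ca.fc2.bias.data
        np.testing.assert_allclose(gate, sigmoid(2 * mlp(c)), atol=1e-10)

    def test_gate_strictly_inside_unit_interval(self, rng):
        ca = ChannelAttention3d(4, reduction=2, rng=rng)
        g = ca.gate(Tensor(rng.standard_normal((2, 4, 3, 3, 3)) * 10)).data
        assert np.all(g > 0) and np.all(g < 1)

    def test_toy_tensor_matches_scalar_oracle(self, rng):
        ca = ChannelAttention3d(2, reduction=1, rng=rng)
        m = rng.standard_normal((1, 2, 2, 2, 2))
        out = ca(Tensor(m)).data[0]
        avg = m[0].mean(axis=(1, 2, 3))
        mx = m[0].max(axis=(1, 2, 3))
        mlp = lambda v: ca.fc2.weight.data.T @ np.maximum(
            ca.fc1.weight.data.T @ v + ca.fc1.bias.data, 0) + ca.fc2.bias.data
        gate = sigmoid(mlp(avg) + mlp(mx))
        np.testing.assert_allclose(out, m[0] * gate[:, None, None, None], atol=1e-10)


class TestSpatialAttention:
    def test_spatially_constant_input_gives_constant_gate(self, rng):
        sa = SpatialAttention3d(kernel=3, rng=rng)
        m = np.tile(np.array([2.0, -1.0])[:, None, None, None], (1, 5, 5, 5))[None]
        gate = sa.gate(Tensor(m)).data[0, 0]
        interior = gate[1:-1, 1:-1, 1:-1]
        np.testing.assert_allclose(interior, interior[0, 0, 0], atol=1e-12)

    def test_gate_bounded(self, rng):
        sa = SpatialAttention3d(kernel=7, rng=rng)
        g = sa.gate(Tensor(rng.standard_normal((1, 3, 4, 4, 4)) * 5)).data
        assert np.all(g > 0) and np.all(g < 1)

    def test_matches_direct_convolution_oracle(self, rng):
        sa = SpatialAttention3d(kernel=7, rng=rng)
        u = rng.standard_normal((1, 1, 3, 3, 3))
        desc = np.concatenate([u.mean(axis=1, keepdims=True),
                               u.max(axis=1, keepdims=True)], axis=1)
        ref = sigmoid(conv3d_forward(desc, sa.conv.weight.data, 1, 3)
                      + sa.conv.bias.data.reshape(1, -1, 1, 1, 1))
        np.testing.assert_allclose(sa.gate(Tensor(u)).data, ref, atol=1e-12)


# ---------------------------------------------------------------------------
# RDA block / tail
# ---------------------------------------------------------------------------

class TestRDA:
    def test_zero_conv_branch_reduces_to_identity(self, rng):
        cfg = ModelConfig.scaled(0.125)
        blk = RDABlock(4, cfg, rng)
        for name, p in blk.named_parameters():
            if name.startswith(("conv1", "conv2", "norm")) and "gamma" not in name:
                p.data = np.zeros_like(p.data)
        x = Tensor(rng.standard_normal((1, 4, 3, 3, 3)))
        # conv branch emits exactly zero; gating multiplies zero by (0,1) gates
        np.testing.assert_allclose(blk(x).data, x.data, atol=1e-12)

    def test_block_preserves_shape(self, rng):
        cfg = ModelConfig.scaled(0.125)
        blk = RDABlock(6, cfg, rng)
        x = Tensor(rng.standard_normal((2, 6, 4, 4, 4)))
        assert blk(x).shape == x.shape

    def test_tail_reaches_4x_channels(self, rng):
        cfg = ModelConfig.scaled(0.25)
        tail = RDATail(cfg, rng)
        c, f = cfg.path_channels, cfg.feature_size
        out = tail(Tensor(rng.standard_normal((1, c, f, f, f)).astype(np.float32)))
        assert out["rda_mid"].shape == (1, 2 * c, f // 2, f // 2, f // 2)
        assert out["rda_out"].shape == (1, 4 * c, f // 4, f // 4, f // 4)
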