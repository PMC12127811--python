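"""High-order feature extractors: a 3-D vision transformer and a residual
dual-attention (channel + spatial, CBAM-style) convolutional tail.

The transformer branch consumes the enhanced path-1 map F7 (a.k.a. F_lambda):
a 3x3x3 convolution lifts channels to the embedding width, every spatial
position of the low-resolution map becomes a token (optionally coarser via
``patch_size``), learnable position embeddings are added, and four pre-norm
transformer layers (multi-head self-attention + MLP, residual around each)
refine the sequence.  No class token is used; the head pools tokens instead.

The dual-attention branch consumes F8 through two strided stages of residual
blocks in which each block's convolutional branch is gated first per channel
(sigmoid of a shared MLP over global average- and max-pooled descriptors)
and then per voxel (sigmoid of a 7x7x7 convolution over the channel-wise
average and max maps) before the residual addition.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import ModelConfig
from .nn import Conv3d, InstanceNorm3d, LayerNorm, Linear, Module, Parameter, Tensor


# ---------------------------------------------------------------------------
# ViT branch
# ---------------------------------------------------------------------------

class PatchEmbed3d(Module):
    """Conv projection to the embedding width + flatten + position embeddings."""

    def __init__(self, c_in: int, embed_dim: int, grid: int, patch_size: int,
                 rng: np.random.Generator, dtype=np.float64):
        if grid % patch_size:
            raise ValueError("patch_size must divide the feature-map size")
        self.tokens_per_axis = grid // patch_size
        self.n_tokens = self.tokens_per_axis**3
        self.embed_dim = embed_dim
        self.proj = Conv3d(c_in, embed_dim, 3, stride=patch_size, pad=1, rng=rng,
                           dtype=dtype)
        self.pos = Parameter(
            (rng.standard_normal((self.n_tokens, embed_dim)) * 0.02).astype(dtype)
        )

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        e = self.proj(x)  # (N, E, g, g, g)
        tokens = e.reshape(n, self.embed_dim, self.n_tokens).transpose(0, 2, 1)
        return tokens + self.pos


class MultiHeadSelfAttention(Module):
    """Scaled dot-product attention: softmax(Q K^T / sqrt(d)) V per head."""

    def __init__(self, embed_dim: int, n_heads: int, rng, dtype=np.float64):
        if embed_dim % n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d = embed_dim // n_heads
        self.wq = Linear(embed_dim, embed_dim, rng, dtype=dtype)
        self.wk = Linear(embed_dim, embed_dim, rng, dtype=dtype)
        self.wv = Linear(embed_dim, embed_dim, rng, dtype=dtype)
        self.wo = Linear(embed_dim, embed_dim, rng, dtype=dtype)

    def _split(self, t: Tensor, n: int, T: int) -> Tensor:
        return t.reshape(n, T, self.n_heads, self.d).transpose(0, 2, 1, 3)

    def forward(self, z: Tensor) -> Tensor:
        n, T, e = z.shape
        # fold the 1/sqrt(d) scale into Q: one fewer full pass over the scores
        # (plain python float so float32 activations are not promoted)
        q = self._split(self.wq(z) * (1.0 / float(np.sqrt(self.d))), n, T)
        k = self._split(self.wk(z), n, T)
        v = self._split(self.wv(z), n, T)
        attn = (q @ k.transpose(0, 1, 3, 2)).softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, T, e)
        return self.wo(out)


class TransformerLayer(Module):
    """Pre-norm block: z + MSA(LN(z)), then + MLP(LN(.))."""

    def __init__(self, embed_dim: int, n_heads: int, mlp_ratio: int, rng,
                 dtype=np.float64):
        self.norm1 = LayerNorm(embed_dim, dtype=dtype)
        self.msa = MultiHeadSelfAttention(embed_dim, n_heads, rng, dtype=dtype)
        self.norm2 = LayerNorm(embed_dim, dtype=dtype)
        self.fc1 = Linear(embed_dim, mlp_ratio * embed_dim, rng, dtype=dtype)
        self.fc2 = Linear(mlp_ratio * embed_dim, embed_dim, rng, dtype=dtype)

    def forward(self, z: Tensor) -> Tensor:
        z = z + self.msa(self.norm1(z))
        return z + self.fc2(self.fc1(self.norm2(z)).relu())


class ViT3d(Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dtype = np.dtype(cfg.dtype).type
        self.embed = PatchEmbed3d(cfg.path_channels, cfg.embed_dim,
                                  cfg.feature_size, cfg.patch_size, rng, dtype=dtype)
        self.layers = [
            TransformerLayer(cfg.embed_dim, cfg.vit_heads, cfg.mlp_ratio, rng,
                             dtype=dtype)
            for _ in range(cfg.vit_layers)
        ]

    def forward(self, f_lambda: Tensor) -> Tensor:
        z = self.embed(f_lambda)
        for layer in self.layers:
            z = layer(z)
        return z  # (N, tokens, E)

    def tokens_to_map(self, z: Tensor) -> Tensor:
        n, T, e = z.shape
        g = self.embed.tokens_per_axis
        return z.transpose(0, 2, 1).reshape(n, e, g, g, g)


# ---------------------------------------------------------------------------
# residual dual-attention branch
# ---------------------------------------------------------------------------

class ChannelAttention3d(Module):
    """sigma(MLP(avgpool) + MLP(maxpool)) per channel, broadcast spatially."""

    def __init__(self, channels: int, reduction: int, rng, dtype=np.float64):
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng, dtype=dtype)
        self.fc2 = Linear(hidden, channels, rng, dtype=dtype)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def gate(self, m: Tensor) -> Tensor:
        avg = m.mean(axis=(2, 3, 4))
        mx = m.reshape(m.shape[0], m.shape[1], -1).max(axis=2)
        g = (self._mlp(avg) + self._mlp(mx)).sigmoid()
        return g.reshape(g.shape[0], g.shape[1], 1, 1, 1)

    def forward(self, m: Tensor) -> Tensor:
        return m * self.gate(m)


class SpatialAttention3d(Module):
    """sigma(conv7([channel-avg; channel-max])) per voxel."""

    def __init__(self, kernel: int, rng, dtype=np.float64):
        self.conv = Conv3d(2, 1, kernel, pad=kernel // 2, rng=rng, dtype=dtype)

    def gate(self, u: Tensor) -> Tensor:
        avg = u.mean(axis=1, keepdims=True)
        mx = u.max(axis=1, keepdims=True)
        return self.conv(nn.concat([avg, mx], axis=1)).sigmoid()

    def forward(self, u: Tensor) -> Tensor:
        return u * self.gate(u)


class RDABlock(Module):
    """Residual block whose conv branch is channel- then spatially-gated.

    output = F' + spatial_att(channel_att(conv_branch(F')))
    """

    def __init__(self, channels: int, cfg: ModelConfig, rng, dtype=np.float64):
        self.norm1 = InstanceNorm3d(channels, dtype=dtype)
        self.conv1 = Conv3d(channels, channels, 3, rng=rng, dtype=dtype)
        self.norm2 = InstanceNorm3d(channels, dtype=dtype)
        self.conv2 = Conv3d(channels, channels, 3, rng=rng, dtype=dtype)
        self.channel_att = ChannelAttention3d(channels, cfg.reduction_ratio, rng,
                                              dtype=dtype)
        self.spatial_att = SpatialAttention3d(cfg.spatial_kernel, rng, dtype=dtype)

    def forward(self, f: Tensor) -> Tensor:
        y = self.conv1(self.norm1(f).relu())
        y = self.conv2(self.norm2(y).relu())
        y = self.channel_att(y)
        y = self.spatial_att(y)
        return f + y


class RDATail(Module):
    """Two strided stages of dual-attention residual blocks on F8.

    Doubles channels twice (128 -> 256 -> 512 at full width); the 256-channel
    intermediate map is kept for the multi-scale classifier pooling.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        from .backbone import Downsample

        dtype = np.dtype(cfg.dtype).type
        c = cfg.path_channels
        self.down1 = Downsample(c, rng, dtype=dtype)
        self.blocks1 = [RDABlock(2 * c, cfg, rng, dtype=dtype) for _ in range(2)]
        self.down2 = Downsample(2 * c, rng, dtype=dtype)
        self.blocks2 = [RDABlock(4 * c, cfg, rng, dtype=dtype) for _ in range(2)]

    def forward(self, f8: Tensor) -> dict[str, Tensor]:
        x = self.down1(f8)
        for b in self.blocks1:
            x = b(x)
        mid = x
        x = self.down2(x)
        for b in self.blocks2:
            x = b(x)
        return {"rda_mid": mid, "rda_out": x}
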