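"""Inter-gene-relationship classifier head.

Feature maps at three scales (the enhanced 128-channel map F6, the
256-channel dual-attention intermediate, and the 512-channel union of the
final transformer and dual-attention features, averaged) are summarized by
parameter-free global average and max pooling and concatenated into a single
vector (1792-dimensional at full width).  Independent fully connected stacks
(1792 -> 1280 -> 512 -> 32 -> 2, softmax) type IDH and ATRX.  The 1p/19q head
runs the same stack to its 32-unit penultimate layer, then concatenates the
two confidence scalars max(P_idh) and max(P_atrx) before the final linear
layer — so the 1p/19q decision is explicitly conditioned on how confidently
the other two genes were typed, and its loss back-propagates into their heads.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import ModelConfig
from .nn import Linear, Module, Tensor


def global_avg_pool(m: Tensor) -> Tensor:
    """Per-channel spatial mean of an (N, C, D, H, W) map -> (N, C)."""
    return m.mean(axis=(2, 3, 4))


def global_max_pool(m: Tensor) -> Tensor:
    """Per-channel spatial max of an (N, C, D, H, W) map -> (N, C)."""
    return m.reshape(m.shape[0], m.shape[1], -1).max(axis=2)


def multiscale_pool(maps: list[Tensor], expected_channels: tuple[int, ...]) -> Tensor:
    """GAP + GMP each map, concatenated in scale order -> (N, 2*sum(C))."""
    if len(maps) != len(expected_channels):
        raise ValueError(f"expected {len(expected_channels)} maps, got {len(maps)}")
    pieces = []
    for m, c in zip(maps, expected_channels):
        if m.shape[1] != c:
            raise ValueError(f"expected channel counts {expected_channels}, "
                             f"got {[x.shape[1] for x in maps]}")
        pieces.extend([global_avg_pool(m), global_max_pool(m)])
    return nn.concat(pieces, axis=1)


class GeneHead(Module):
    """FC stack pooled -> 1280 -> 512 -> 32 -> 2 with softmax output."""

    def __init__(self, in_dim: int, widths: tuple[int, ...], rng, dtype=np.float64):
        dims = (in_dim, *widths)
        self.hidden = [Linear(dims[i], dims[i + 1], rng, dtype=dtype)
                       for i in range(len(dims) - 1)]
        self.out = Linear(dims[-1], 2, rng, dtype=dtype)

    def penultimate(self, feat: Tensor) -> Tensor:
        x = feat
        for layer in self.hidden:
            x = layer(x).relu()
        return x

    def forward(self, feat: Tensor) -> tuple[Tensor, Tensor]:
        logits = self.out(self.penultimate(feat))
        return logits, logits.softmax(axis=-1)


class CodelHead(Module):
    """1p/19q head, optionally conditioned on the IDH/ATRX confidences."""

    def __init__(self, in_dim: int, widths: tuple[int, ...], rng,
                 use_igt: bool = True, dtype=np.float64):
        dims = (in_dim, *widths)
        self.use_igt = use_igt
        self.hidden = [Linear(dims[i], dims[i + 1], rng, dtype=dtype)
                       for i in range(len(dims) - 1)]
        self.out = Linear(dims[-1] + (2 if use_igt else 0), 2, rng, dtype=dtype)

    def forward(self, feat: Tensor, p_idh: Tensor | None = None,
                p_atrx: Tensor | None = None) -> tuple[Tensor, Tensor]:
        x = feat
        for layer in self.hidden:
            x = layer(x).relu()
        if self.use_igt:
            if p_idh is None or p_atrx is None:
                raise ValueError("conditioned 1p/19q head needs p_idh and p_atrx")
            conf_i = p_idh.max(axis=1, keepdims=True)   # in [0.5, 1]
            conf_a = p_atrx.max(axis=1, keepdims=True)
            x = nn.concat([x, conf_i, conf_a], axis=1)
        logits = self.out(x)
        return logits, logits.softmax(axis=-1)


class GenotypingHead(Module):
    """Multi-scale pooling plus the three gene heads."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dtype = np.dtype(cfg.dtype).type
        c = cfg.path_channels
        self.scale_channels = (c, 2 * c, 4 * c)
        in_dim = cfg.pooled_dim
        self.idh = GeneHead(in_dim, cfg.fc_widths, rng, dtype=dtype)
        self.atrx = GeneHead(in_dim, cfg.fc_widths, rng, dtype=dtype)
        self.codel = CodelHead(in_dim, cfg.fc_widths, rng, use_igt=cfg.use_igt,
                               dtype=dtype)

    def pool(self, f6: Tensor, rda_mid: Tensor, vit_map: Tensor,
             rda_out: Tensor) -> Tensor:
        # the deepest scale is the average of the two branch outputs, pooled
        # separately (their spatial grids differ)
        c = self.scale_channels
        gap512 = (global_avg_pool(vit_map) + global_avg_pool(rda_out)) * 0.5
        gmp512 = (global_max_pool(vit_map) + global_max_pool(rda_out)) * 0.5
        pooled128 = multiscale_pool([f6], (c[0],))
        pooled256 = multiscale_pool([rda_mid], (c[1],))
        if vit_map.shape[1] != c[2] or rda_out.shape[1] != c[2]:
            raise ValueError("deepest-scale channel mismatch")
        return nn.concat([pooled128, pooled256, gap512, gmp512], axis=1)

    def forward(self, f6, rda_mid, vit_map, rda_out):
        feat = self.pool(f6, rda_mid, vit_map, rda_out)
        logits_i, p_i = self.idh(feat)
        logits_a, p_a = self.atrx(feat)
        logits_c, p_c = self.codel(feat, p_i, p_a)
        return {
            "pooled": feat,
            "logits": {"idh": logits_i, "atrx": logits_a, "codel_1p19q": logits_c},
            "probs": {"idh": p_i, "atrx": p_a, "codel_1p19q": p_c},
        }
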