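"""Asymmetric dual-path 3-D convolutional front end.

Two parallel residual-conv paths process (a) the 4-modality stack and (b) the
T2+FLAIR pair.  After the stems, low-level features are exchanged once
(concatenate -> conv -> residual addition into both paths).  Three stride-2
downsamples (channels doubling each time) bring a 128^3 input to a 16^3 map
with 128 channels per path (F3, F4).  The mid-network enhancement then
concatenates the two maps (F5, 256 ch), reduces back with a 1x1x1 conv
(F6, 128 ch) and re-injects residually into each path: F7 = F6 + F3 feeds the
transformer branch, F8 = F6 + F4 feeds the dual-attention branch.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import ModelConfig
from .nn import Conv3d, InstanceNorm3d, Module, Tensor


class ResidualBlock(Module):
    """Pre-activation residual block: y = x + conv(relu(norm(conv(relu(norm(x))))))."""

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float64):
        self.norm1 = InstanceNorm3d(channels, dtype=dtype)
        self.conv1 = Conv3d(channels, channels, 3, rng=rng, dtype=dtype)
        self.norm2 = InstanceNorm3d(channels, dtype=dtype)
        self.conv2 = Conv3d(channels, channels, 3, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv1(self.norm1(x).relu())
        y = self.conv2(self.norm2(y).relu())
        return x + y


class Downsample(Module):
    """Strided 3x3x3 convolution halving spatial size and doubling channels."""

    def __init__(self, c_in: int, rng: np.random.Generator, c_out: int | None = None,
                 dtype=np.float64):
        self.conv = Conv3d(c_in, c_out or 2 * c_in, 3, stride=2, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


class PathStage(Module):
    def __init__(self, c_in: int, n_blocks: int, rng, dtype=np.float64):
        self.down = Downsample(c_in, rng, dtype=dtype)
        self.blocks = [ResidualBlock(2 * c_in, rng, dtype=dtype) for _ in range(n_blocks)]

    def forward(self, x: Tensor) -> Tensor:
        x = self.down(x)
        for b in self.blocks:
            x = b(x)
        return x


class EarlyFusion(Module):
    """One low-level information exchange between the paths.

    concat(low1, low2) -> 3x3x3 conv back to the stem width; the fused map is
    added residually into both paths, so each keeps its own features plus a
    shared summary.
    """

    def __init__(self, channels: int, rng, dtype=np.float64):
        self.conv = Conv3d(2 * channels, channels, 3, rng=rng, dtype=dtype)

    def forward(self, low1: Tensor, low2: Tensor) -> tuple[Tensor, Tensor]:
        if low1.shape != low2.shape:
            raise ValueError(f"spatial mismatch: {low1.shape} vs {low2.shape}")
        fused = self.conv(nn.concat([low1, low2], axis=1))
        return low1 + fused, low2 + fused


class FeatureEnhancement(Module):
    """Mid-network exchange producing the enhanced maps F7 and F8."""

    def __init__(self, channels: int, rng, dtype=np.float64):
        self.reduce = Conv3d(2 * channels, channels, kernel=1, pad=0, rng=rng,
                             dtype=dtype)

    def forward(self, f3: Tensor, f4: Tensor) -> dict[str, Tensor]:
        if f3.shape != f4.shape:
            raise ValueError(f"channel/shape mismatch: {f3.shape} vs {f4.shape}")
        f5 = nn.concat([f3, f4], axis=1)
        f6 = self.reduce(f5)
        return {"F5": f5, "F6": f6, "F7": f6 + f3, "F8": f6 + f4}


class DualPathBackbone(Module):
    """Full front end; ``forward`` returns the named stage maps."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        cfg.validate()
        dtype = np.dtype(cfg.dtype).type
        c = cfg.base_channels
        self.cfg = cfg
        self.stem1 = Conv3d(cfg.in_channels, c, 3, rng=rng, dtype=dtype)
        self.stem2 = Conv3d(2, c, 3, rng=rng, dtype=dtype)
        self.fusion = EarlyFusion(c, rng, dtype=dtype)
        self.path1 = [
            PathStage(c * 2**i, cfg.blocks_per_stage, rng, dtype=dtype)
            for i in range(cfg.n_stages)
        ]
        self.path2 = [
            PathStage(c * 2**i, cfg.blocks_per_stage, rng, dtype=dtype)
            for i in range(cfg.n_stages)
        ]
        self.enhance = FeatureEnhancement(cfg.path_channels, rng, dtype=dtype)

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        if x.ndim != 5 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected (N, {self.cfg.in_channels}, D, H, W), got {x.shape}")
        if any(s != self.cfg.input_size for s in x.shape[2:]):
            raise ValueError(
                f"expected cubic spatial size {self.cfg.input_size}, got {x.shape[2:]}"
            )
        low1 = self.stem1(x)
        low2 = self.stem2(x[:, 2:4])  # T2 + FLAIR channels
        f1, f2 = self.fusion(low1, low2)
        for stage in self.path1:
            f1 = stage(f1)
        for stage in self.path2:
            f2 = stage(f2)
        stages = {"low1": low1, "low2": low2, "F3": f1, "F4": f2}
        stages.update(self.enhance(f1, f2))
        return stages
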