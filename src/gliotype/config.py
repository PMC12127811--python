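"""Configuration dataclasses for the network, training and phantom cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

MODALITIES = ("t1", "t1ce", "t2", "flair")
GENES = ("idh", "atrx", "codel_1p19q")

#: modality-availability patterns the cohorts emulate, in weight order:
#: all four / T1+T2+FLAIR (no contrast) / T1ce+T2+FLAIR (no plain T1).
MISSING_PATTERNS = (
    (1, 1, 1, 1),
    (1, 0, 1, 1),
    (0, 1, 1, 1),
)


@dataclass
class ModelConfig:
    """Architecture widths; the defaults are the full-size network.

    ``scaled`` shrinks widths, embedding size and input resolution jointly so
    the identical architecture trains on a CPU in minutes.
    """

    in_channels: int = 4
    input_size: int = 128          # cubic crop fed to the network
    base_channels: int = 16        # stem width; doubles at each of 3 downsamples
    n_stages: int = 3              # 128^3 -> 16^3
    blocks_per_stage: int = 2
    embed_dim: int = 512           # ViT token width
    vit_layers: int = 4
    vit_heads: int = 8
    mlp_ratio: int = 4
    patch_size: int = 1            # one token per spatial position of the 16^3 map
    reduction_ratio: int = 16      # channel-attention bottleneck
    spatial_kernel: int = 7
    fc_widths: tuple[int, ...] = (1280, 512, 32)
    use_igt: bool = True           # condition the 1p/19q head on IDH/ATRX outputs
    dtype: str = "float64"

    @property
    def path_channels(self) -> int:
        """Channels of each path's pre-fusion feature map (F3/F4)."""
        return self.base_channels * 2**self.n_stages

    @property
    def feature_size(self) -> int:
        return self.input_size // 2**self.n_stages

    @property
    def pooled_dim(self) -> int:
        c = self.path_channels
        return 2 * (c + 2 * c + 4 * c)

    @classmethod
    def scaled(cls, scale: float = 1.0, **overrides) -> "ModelConfig":
        base = max(2, int(round(16 * scale)))
        heads = max(1, int(round(8 * scale)))
        embed = max(heads * 8, int(round(512 * scale)))
        embed -= embed % heads
        fc = tuple(max(4, int(round(w * scale))) for w in (1280, 512, 32))
        cfg = cls(
            input_size=max(8, 8 * int(round(16 * scale))),
            base_channels=base,
            embed_dim=embed,
            vit_heads=heads,
            fc_widths=fc,
        )
        return replace(cfg, **overrides)

    def validate(self) -> None:
        if self.input_size % 2**self.n_stages:
            raise ValueError("input_size must be divisible by 2**n_stages")
        if self.embed_dim % self.vit_heads:
            raise ValueError("embed_dim must be divisible by vit_heads")
        if self.feature_size % self.patch_size:
            raise ValueError("patch_size must divide the feature-map size")


@dataclass
class LossConfig:
    """LMF mixing and per-task uncertainty initialization."""

    alpha: float = 0.5             # LDAM weight in the LMF sum
    beta: float = 0.5              # focal weight
    gamma: float = 2.0             # focal focusing exponent
    focal_alpha: str | Sequence[float] = "inverse_frequency"
    ldam_max_margin: float = 0.5
    ldam_delta: float = 0.0        # margin floor
    sigma_init: tuple[float, float, float] = (5.0, 6.0, 6.0)  # idh, 1p/19q, atrx


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 2
    epochs: int = 1000
    flip_prob: float = 0.5
    augment: bool = True
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def validate(self) -> None:
        if self.lr <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("lr, batch_size and epochs must be positive")


@dataclass
class CohortSpec:
    """Study conditions for a synthetic phantom cohort.

    Defaults follow the cohort the method was developed on: IDH-mutant 33%,
    ATRX-mutant 20%, 1p/19q-codeleted 11% of subjects, and the clinical
    missing-modality mix (16.8% full, 49.5% without T1-ce, 33.7% without T1).
    """

    n_subjects: int = 100
    volume_shape: tuple[int, int, int] = (240, 240, 155)
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"idh": 0.33, "atrx": 0.20, "codel_1p19q": 0.11}
    )
    rule_adherence: float = 1.0
    missing_modality_weights: tuple[float, float, float] = (1.0, 0.0, 0.0)
    lesion_radius_range: tuple[float, float] = (12.0, 30.0)
    edema_prob: float = 0.85
    codel_blur_sigma: float = 2.0
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        for g, f in self.class_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"class fraction for {g} outside [0,1]")
        if not 0.0 <= self.rule_adherence <= 1.0:
            raise ValueError("rule_adherence outside [0,1]")
        w = np.asarray(self.missing_modality_weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("missing_modality_weights must be nonnegative, not all zero")
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise ValueError("lesion radii must be positive and ordered")
        if hi >= min(self.volume_shape) / 2:
            raise ValueError("max lesion radius must fit in half the smallest dimension")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)
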