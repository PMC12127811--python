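"""Volume preprocessing: z-score normalization, modality stacking, crop/flip.

Normalization is computed per modality per subject over the nonzero (brain)
voxels only, so the zero background of skull-stripped volumes does not skew
the statistics and stays exactly zero.  Missing modalities are zero-filled
*after* normalization, so an absent channel is identically zero and therefore
indistinguishable from "no signal" for the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MODALITIES
from .synthetic import SubjectSample

__all__ = [
    "ModelInput",
    "zscore_normalize",
    "stack_modalities",
    "random_crop",
    "center_crop",
    "random_flip",
    "build_model_input",
]


@dataclass
class ModelInput:
    """A 4-channel volume (T1, T1-ce, T2, FLAIR order) plus availability flags."""

    tensor: np.ndarray                       # (4, D, H, W)
    availability_mask: tuple[int, int, int, int]

    def __post_init__(self):
        if self.tensor.ndim != 4 or self.tensor.shape[0] != 4:
            raise ValueError(f"expected a (4, D, H, W) tensor, got {self.tensor.shape}")


def zscore_normalize(volume: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Standardize to mean 0 / SD 1 over ``mask`` (default: nonzero voxels).

    Background (out-of-mask) voxels are left at exactly zero.
    """
    volume = np.asarray(volume, dtype=np.float32)
    if mask is None:
        mask = volume != 0
    vals = volume[mask]
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("volume is constant within the normalization region")
    mu = vals.mean(dtype=np.float64)
    sd = vals.std(dtype=np.float64)
    out = np.zeros_like(volume)
    out[mask] = ((vals - mu) / sd).astype(np.float32)
    return out


def stack_modalities(sample: SubjectSample, normalize: bool = True) -> ModelInput:
    """Stack per-modality volumes into the fixed channel order, zero-filling gaps.

    The T2/FLAIR path of the network requires both modalities, so their
    absence is an error rather than a zero-fill.
    """
    for required in ("t2", "flair"):
        if required not in sample.volumes:
            raise ValueError(f"required modality {required!r} is missing")
    shape = next(iter(sample.volumes.values())).shape
    channels = []
    for mod in MODALITIES:
        if mod in sample.volumes:
            vol = sample.volumes[mod]
            if vol.shape != shape:
                raise ValueError(f"modality {mod} shape {vol.shape} != {shape}")
            channels.append(zscore_normalize(vol) if normalize else vol)
        else:
            channels.append(np.zeros(shape, dtype=np.float32))
    return ModelInput(
        tensor=np.stack(channels, axis=0), availability_mask=sample.availability_mask
    )


def _pad_to(tensor: np.ndarray, size: int) -> np.ndarray:
    """Symmetric zero-padding of spatial axes up to ``size`` (no-op if larger)."""
    pads = [(0, 0)]
    for s in tensor.shape[1:]:
        missing = max(0, size - s)
        pads.append((missing // 2, missing - missing // 2))
    if any(p != (0, 0) for p in pads):
        tensor = np.pad(tensor, pads)
    return tensor


def random_crop(
    inp: ModelInput, rng: np.random.Generator, size: int = 128
) -> ModelInput:
    """Uniform random spatial crop to ``size``^3, same window for all channels."""
    t = _pad_to(inp.tensor, size)
    offsets = [int(rng.integers(0, s - size + 1)) for s in t.shape[1:]]
    window = tuple(slice(o, o + size) for o in offsets)
    return ModelInput(t[(slice(None),) + window].copy(), inp.availability_mask)


def center_crop(inp: ModelInput, size: int = 128) -> ModelInput:
    """Deterministic center crop used at validation/test time."""
    t = _pad_to(inp.tensor, size)
    window = tuple(slice((s - size) // 2, (s - size) // 2 + size) for s in t.shape[1:])
    return ModelInput(t[(slice(None),) + window].copy(), inp.availability_mask)


def random_flip(
    inp: ModelInput, rng: np.random.Generator, p: float = 0.5
) -> ModelInput:
    """Independently reverse each spatial axis with probability ``p``."""
    t = inp.tensor
    axes = [ax for ax in (1, 2, 3) if rng.random() < p]
    if axes:
        t = np.flip(t, axis=axes).copy()
    return ModelInput(t, inp.availability_mask)


def build_model_input(sample: SubjectSample) -> ModelInput:
    """Normalize and stack one subject (full-volume, pre-crop)."""
    return stack_modalities(sample, normalize=True)
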