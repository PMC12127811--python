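"""3-D convolution and norm primitives for the autodiff core.

The forward convolution is an im2col matmul, chunked along the output depth
axis so the unfolded column buffer stays below ~256 MB even for full-size
(128^3) volumes.  Backward passes loop over the k^3 kernel offsets, which
keeps memory flat and is fast at the training scales this package uses.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

_COL_BYTES_LIMIT = 256 * 1024 * 1024


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def conv3d_forward(
    x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 1
) -> np.ndarray:
    """Cross-correlate ``x`` (N,C,D,H,W) with ``w`` (Co,C,k,k,k)."""
    n, c, d, h, wd = x.shape
    co, ci, k, _, _ = w.shape
    if ci != c:
        raise ValueError(f"channel mismatch: input {c}, kernel {ci}")
    do = _out_size(d, k, stride, pad)
    ho = _out_size(h, k, stride, pad)
    wo = _out_size(wd, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad))) if pad else x
    wmat = np.ascontiguousarray(w.reshape(co, c * k * k * k))
    out = np.empty((n, co, do, ho, wo), dtype=x.dtype)

    bytes_per_slab = n * c * k * k * k * ho * wo * x.dtype.itemsize
    zchunk = max(1, _COL_BYTES_LIMIT // max(1, bytes_per_slab))
    for z0 in range(0, do, zchunk):
        z1 = min(z0 + zchunk, do)
        nz = z1 - z0
        cols = np.empty((n, c, k, k, k, nz, ho, wo), dtype=x.dtype)
        for kd in range(k):
            d0 = z0 * stride + kd
            for kh in range(k):
                for kw in range(k):
                    cols[:, :, kd, kh, kw] = xp[
                        :,
                        :,
                        d0 : d0 + (nz - 1) * stride + 1 : stride,
                        kh : kh + (ho - 1) * stride + 1 : stride,
                        kw : kw + (wo - 1) * stride + 1 : stride,
                    ]
        flat = cols.reshape(n, c * k * k * k, nz * ho * wo)
        out[:, :, z0:z1] = np.matmul(wmat, flat).reshape(n, co, nz, ho, wo)
    return out


def conv3d_input_grad(
    g: np.ndarray, w: np.ndarray, x_shape, stride: int, pad: int
) -> np.ndarray:
    n, c, d, h, wd = x_shape
    co, ci, k, _, _ = w.shape
    _, _, do, ho, wo = g.shape
    gxp = np.zeros((n, c, d + 2 * pad, h + 2 * pad, wd + 2 * pad), dtype=g.dtype)
    for kd in range(k):
        for kh in range(k):
            for kw in range(k):
                # (N,Co,do,ho,wo) x (Co,C) -> (N,C,do,ho,wo)
                contrib = np.einsum("nodhw,oc->ncdhw", g, w[:, :, kd, kh, kw])
                gxp[
                    :,
                    :,
                    kd : kd + (do - 1) * stride + 1 : stride,
                    kh : kh + (ho - 1) * stride + 1 : stride,
                    kw : kw + (wo - 1) * stride + 1 : stride,
                ] += contrib
    if pad:
        gxp = gxp[:, :, pad:-pad, pad:-pad, pad:-pad]
    return gxp


def conv3d_weight_grad(
    x: np.ndarray, g: np.ndarray, w_shape, stride: int, pad: int
) -> np.ndarray:
    co, c, k, _, _ = w_shape
    _, _, do, ho, wo = g.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad))) if pad else x
    gw = np.empty(w_shape, dtype=g.dtype)
    for kd in range(k):
        for kh in range(k):
            for kw in range(k):
                xs = xp[
                    :,
                    :,
                    kd : kd + (do - 1) * stride + 1 : stride,
                    kh : kh + (ho - 1) * stride + 1 : stride,
                    kw : kw + (wo - 1) * stride + 1 : stride,
                ]
                gw[:, :, kd, kh, kw] = np.tensordot(
                    g, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4])
                )
    return gw


def conv3d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    pad: int = 1,
) -> Tensor:
    """Differentiable 3-D convolution (cross-correlation), NCDHW layout."""
    data = conv3d_forward(x.data, w.data, stride, pad)
    if b is not None:
        data = data + b.data.reshape(1, -1, 1, 1, 1)

    def bw(g):
        gx = (
            conv3d_input_grad(g, w.data, x.shape, stride, pad)
            if x.requires_grad
            else None
        )
        gw = (
            conv3d_weight_grad(x.data, g, w.shape, stride, pad)
            if w.requires_grad
            else None
        )
        if b is None:
            return gx, gw
        gb = g.sum(axis=(0, 2, 3, 4)) if b.requires_grad else None
        return gx, gw, gb

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(data, parents, bw)


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel standardization over spatial axes (NCDHW)."""
    mu = x.mean(axis=(2, 3, 4), keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
    y = xc * ((var + eps) ** -0.5)
    return y * gamma.reshape(1, -1, 1, 1, 1) + beta.reshape(1, -1, 1, 1, 1)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Standardize the last axis (token embeddings)."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * ((var + eps) ** -0.5) * gamma + beta
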