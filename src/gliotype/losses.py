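"""Imbalance-aware loss stack.

Per gene, the training objective is the LMF loss

    L = alpha * L_LDAM + beta * L_FL

mixing a label-distribution-aware margin loss (per-class margins proportional
to n_j^{-1/4}, largest for the rarest class) with a focal loss
(-alpha_t (1-p_t)^gamma log p_t).  The three per-gene losses are combined by
homoscedastic-uncertainty weighting,

    L_mul = sum_g L_g / (3 sigma_g^2) + log(sigma_idh sigma_1p19q sigma_atrx),

where the sigma_g are learnable (parameterized on the log scale so they stay
positive) and initialized to 5.0 (IDH), 6.0 (1p/19q), 6.0 (ATRX).  The
stationary point in sigma for a fixed sub-loss L is sigma = sqrt(2 L / 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import GENES, LossConfig
from .nn import Module, Parameter, Tensor, as_tensor

_EPS = 1e-12  # probability clamp used before taking logs


@dataclass
class ClassPriorTable:
    """Training-split class counts and the margins/weights derived from them."""

    counts: np.ndarray                    # (2,) class counts, order (0, 1)
    max_margin: float = 0.5
    delta: float = 0.0                    # margin floor
    margins: np.ndarray = field(init=False)
    inv_freq_weights: np.ndarray = field(init=False)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (2,) or (counts <= 0).any():
            raise ValueError("need positive counts for both classes")
        self.counts = counts
        raw = counts ** -0.25
        self.margins = np.maximum(self.max_margin * raw / raw.max(), self.delta)
        w = counts.sum() / (2.0 * counts)   # inverse-frequency, mean-normalized
        self.inv_freq_weights = w

    @classmethod
    def from_labels(cls, labels: np.ndarray, max_margin: float = 0.5,
                    delta: float = 0.0) -> "ClassPriorTable":
        labels = np.asarray(labels)
        counts = np.array([(labels == 0).sum(), (labels == 1).sum()], dtype=float)
        return cls(counts, max_margin, delta)


def _target_index(targets) -> np.ndarray:
    t = np.asarray(targets, dtype=np.int64)
    if t.ndim != 1:
        raise ValueError("targets must be a 1-D class-index array")
    if ((t < 0) | (t > 1)).any():
        raise ValueError("unknown class in targets (binary tasks only)")
    return t


def focal_loss(probs: Tensor | np.ndarray, targets, alpha_t=1.0,
               gamma: float = 2.0) -> Tensor:
    """Mean of -alpha_t (1 - p_t)^gamma log(p_t) over the batch.

    ``alpha_t`` is a scalar or per-class weight vector indexed by the target.
    p_t is clamped at 1e-12 before the log.
    """
    probs = as_tensor(probs)
    t = _target_index(targets)
    p_t = probs.gather(t[:, None], axis=1).reshape(-1).clip_min(_EPS)
    a = np.asarray(alpha_t, dtype=float)
    a_t = Tensor(a[t] if a.ndim == 1 else a)
    loss = (a_t * (1.0 - p_t) ** gamma) * (-1.0 * p_t.log())
    return loss.mean()


def ldam_loss(logits: Tensor | np.ndarray, targets,
              priors: ClassPriorTable) -> Tensor:
    """Margin-adjusted softmax cross-entropy (mean over the batch).

    The target-class logit is reduced by its class margin before the softmax
    cross-entropy, pushing rare-class decision boundaries outward.
    """
    logits = as_tensor(logits)
    t = _target_index(targets)
    onehot = np.zeros(logits.shape, dtype=logits.dtype)
    onehot[np.arange(t.size), t] = 1.0
    shift = Tensor(onehot * priors.margins[None, :].astype(logits.dtype))
    adjusted = logits - shift
    ce = adjusted.logsumexp(axis=1) - adjusted.gather(t[:, None], axis=1).reshape(-1)
    return ce.mean()


def lmf_loss(logits: Tensor | np.ndarray, targets, priors: ClassPriorTable,
             cfg: LossConfig) -> Tensor:
    """alpha * LDAM + beta * focal (focal on the softmax of the raw logits)."""
    logits = as_tensor(logits)
    alpha_t = (priors.inv_freq_weights
               if cfg.focal_alpha == "inverse_frequency" else cfg.focal_alpha)
    out = None
    if cfg.alpha:
        out = cfg.alpha * ldam_loss(logits, targets, priors)
    if cfg.beta:
        fl = cfg.beta * focal_loss(logits.softmax(axis=1), targets, alpha_t,
                                   cfg.gamma)
        out = fl if out is None else out + fl
    return out if out is not None else as_tensor(0.0)


class MultiTaskUncertainty(Module):
    """Learnable homoscedastic-uncertainty weighting of the three gene losses.

    ``log_sigma`` holds (log sigma_idh, log sigma_1p19q, log sigma_atrx).
    """

    ORDER = ("idh", "codel_1p19q", "atrx")

    def __init__(self, sigma_init=(5.0, 6.0, 6.0), dtype=np.float64):
        init = np.log(np.asarray(sigma_init, dtype=dtype))
        self.log_sigma = Parameter(init)

    @property
    def sigmas(self) -> np.ndarray:
        return np.exp(self.log_sigma.data)

    def forward(self, losses: dict[str, Tensor]) -> Tensor:
        total = self.log_sigma.sum()
        for i, gene in enumerate(self.ORDER):
            inv = (self.log_sigma[i] * -2.0).exp() * (1.0 / 3.0)
            total = total + losses[gene] * inv
        return total


def multitask_loss(l_idh, l_codel, l_atrx, sigmas) -> Tensor:
    """Functional form of the uncertainty-weighted objective (sigmas fixed)."""
    s = np.asarray(sigmas, dtype=float)
    if (s <= 0).any():
        raise ValueError("sigmas must be strictly positive")
    losses = [as_tensor(v) for v in (l_idh, l_codel, l_atrx)]
    total = as_tensor(float(np.log(s).sum()))
    for li, si in zip(losses, s):
        total = total + li * (1.0 / (3.0 * si**2))
    return total


def gene_priors(labels: np.ndarray, cfg: LossConfig) -> dict[str, ClassPriorTable]:
    """Per-gene prior tables from an (N, 3) label matrix in GENES order."""
    labels = np.asarray(labels)
    return {
        g: ClassPriorTable.from_labels(labels[:, i], cfg.ldam_max_margin,
                                       cfg.ldam_delta)
        for i, g in enumerate(GENES)
    }
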