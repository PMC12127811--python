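"""Full genotyping network: dual-path backbone -> ViT / dual-attention -> head."""

from __future__ import annotations

import numpy as np

from .attention import RDATail, ViT3d
from .backbone import DualPathBackbone
from .config import ModelConfig
from .heads import GenotypingHead
from .nn import Module, Tensor, no_grad


class GenotypeNet(Module):
    """End-to-end model predicting IDH, ATRX and 1p/19q status from a 4-channel
    volume.  ``forward`` returns per-gene logits and probabilities; pass
    ``return_features=True`` to also get the named stage maps (F3..F8, the
    branch outputs and the pooled vector) for inspection/export.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        cfg.validate()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.backbone = DualPathBackbone(cfg, rng)
        self.vit = ViT3d(cfg, rng)
        self.rda = RDATail(cfg, rng)
        self.head = GenotypingHead(cfg, rng)

    def forward(self, x: Tensor, return_features: bool = False):
        stages = self.backbone(x)
        tokens = self.vit(stages["F7"])
        vit_map = self.vit.tokens_to_map(tokens)
        rda_maps = self.rda(stages["F8"])
        out = self.head(stages["F6"], rda_maps["rda_mid"], vit_map,
                        rda_maps["rda_out"])
        if return_features:
            out["features"] = {
                **stages, **rda_maps, "tokens": tokens, "vit_map": vit_map,
            }
        return out

    def predict_proba(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Inference: per-gene (N, 2) probabilities, no graph recorded."""
        with no_grad():
            out = self.forward(Tensor(np.asarray(x, dtype=self.cfg.dtype)))
        return {g: p.data.copy() for g, p in out["probs"].items()}
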