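"""Training loop, model selection, metrics, checkpointing and feature export.

Training follows the original recipe: Adam (lr 1e-4, weight decay 1e-5),
batch size 2, random 128^3 crops with random flips, the per-gene LMF losses
combined by the learnable uncertainty weighting, and model selection at the
epoch of minimum validation loss (validation uses deterministic center crops
and the objective with the uncertainty weights frozen at their current
values).  Everything is seed-deterministic on CPU.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .config import GENES, ModelConfig, TrainConfig
from .losses import MultiTaskUncertainty, gene_priors, lmf_loss, multitask_loss
from .model import GenotypeNet
from .nn import Adam, Tensor, no_grad
from .preprocess import ModelInput, build_model_input, center_crop, random_crop, random_flip
from .synthetic import SubjectSample

__all__ = [
    "EvalReport",
    "TrainResult",
    "train",
    "evaluate",
    "binary_metrics",
    "export_feature_maps",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def binary_metrics(y_true: np.ndarray, scores: np.ndarray,
                   y_pred: np.ndarray) -> dict:
    """Acc/AUC/Sens/Spec plus confusion counts for one binary task.

    Sensitivity is the true-positive rate on the positive (mutant/codeleted)
    class; AUC is the Mann-Whitney rank statistic and is reported as NaN when
    the evaluation set contains a single class.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    n = y_true.size
    auc = (roc_auc_score(y_true, scores)
           if len(np.unique(y_true)) == 2 else float("nan"))
    return {
        "acc": (tp + tn) / n if n else float("nan"),
        "auc": float(auc),
        "sens": tp / (tp + fn) if (tp + fn) else float("nan"),
        "spec": tn / (tn + fp) if (tn + fp) else float("nan"),
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
    }


@dataclass
class EvalReport:
    per_gene: dict[str, dict]
    predictions: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_gene).T[["acc", "auc", "sens", "spec"]]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: GenotypeNet
    uncertainty: MultiTaskUncertainty
    history: pd.DataFrame
    best_epoch: int
    priors: dict
    model_cfg: ModelConfig
    train_cfg: TrainConfig
    best_state: dict = field(repr=False, default_factory=dict)


def _prepare(samples: list[SubjectSample]) -> tuple[list[ModelInput], np.ndarray]:
    inputs = [build_model_input(s) for s in samples]
    labels = np.stack([s.labels.as_array() for s in samples])
    return inputs, labels


def _batch(inputs: list[ModelInput], dtype) -> Tensor:
    return Tensor(np.stack([i.tensor for i in inputs]).astype(dtype))


def _gene_losses(out, labels: np.ndarray, priors, loss_cfg) -> dict[str, Tensor]:
    return {
        g: lmf_loss(out["logits"][g], labels[:, i], priors[g], loss_cfg)
        for i, g in enumerate(GENES)
    }


def train(
    train_samples: list[SubjectSample],
    val_samples: list[SubjectSample],
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    early_stop_train_acc: float | None = None,
) -> TrainResult:
    """Fit the network; returns the model restored to the best-validation epoch."""
    if not train_samples or not val_samples:
        raise ValueError("train and validation sets must be nonempty")
    cfg.validate()
    model_cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    dtype = np.dtype(model_cfg.dtype).type

    tr_inputs, tr_labels = _prepare(train_samples)
    va_inputs, va_labels = _prepare(val_samples)
    va_crops = [center_crop(i, model_cfg.input_size) for i in va_inputs]

    priors = gene_priors(tr_labels, cfg.loss)
    model = GenotypeNet(model_cfg, seed=int(rng.integers(2**31)))
    uncertainty = MultiTaskUncertainty(cfg.loss.sigma_init, dtype=dtype)
    params = model.parameters() + uncertainty.parameters()
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

    records = []
    best = {"epoch": -1, "val_loss": np.inf, "state": None, "sigma": None}
    n = len(tr_inputs)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses, correct = [], np.zeros(3)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            crops = []
            for i in idx:
                if cfg.augment:
                    ci = random_crop(tr_inputs[i], rng, model_cfg.input_size)
                    ci = random_flip(ci, rng, cfg.flip_prob)
                else:
                    ci = center_crop(tr_inputs[i], model_cfg.input_size)
                crops.append(ci)
            x = _batch(crops, dtype)
            y = tr_labels[idx]
            out = model(x)
            losses = _gene_losses(out, y, priors, cfg.loss)
            total = uncertainty(losses)
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(sub-losses: { {g: float(l.data) for g, l in losses.items()} })"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_losses.append(float(total.data))
            for gi, g in enumerate(GENES):
                pred = out["probs"][g].data.argmax(axis=1)
                correct[gi] += (pred == y[:, gi]).sum()

        train_acc = correct / n
        val_loss, _ = _validation_loss(model, uncertainty, va_crops, va_labels,
                                       priors, cfg, dtype)
        sig = uncertainty.sigmas
        records.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "sigma_idh": sig[0], "sigma_1p19q": sig[1], "sigma_atrx": sig[2],
            **{f"train_acc_{g}": train_acc[i] for i, g in enumerate(GENES)},
        })
        if val_loss < best["val_loss"]:
            best.update(epoch=epoch, val_loss=val_loss,
                        state=model.state_dict(),
                        sigma=uncertainty.log_sigma.data.copy())
        if early_stop_train_acc is not None and (train_acc >= early_stop_train_acc).all():
            break

    if best["state"] is not None:
        model.load_state_dict(best["state"])
        uncertainty.log_sigma.data = best["sigma"].copy()
    return TrainResult(
        model=model, uncertainty=uncertainty, history=pd.DataFrame(records),
        best_epoch=int(best["epoch"]), priors=priors, model_cfg=model_cfg,
        train_cfg=cfg, best_state=best["state"] or {},
    )


def _validation_loss(model, uncertainty, crops, labels, priors, cfg, dtype):
    with no_grad():
        x = _batch(crops, dtype)
        out = model(x)
        losses = _gene_losses(out, labels, priors, cfg.loss)
        sig = uncertainty.sigmas
        total = multitask_loss(losses["idh"], losses["codel_1p19q"],
                               losses["atrx"], sig)
    return float(total.data), out


# ---------------------------------------------------------------------------
# evaluation / inference
# ---------------------------------------------------------------------------

def predict(model: GenotypeNet, samples: list[SubjectSample]) -> pd.DataFrame:
    """Center-crop inference; returns the per-subject probability/label table."""
    size = model.cfg.input_size
    dtype = np.dtype(model.cfg.dtype).type
    rows = []
    for s in samples:
        crop = center_crop(build_model_input(s), size)
        probs = model.predict_proba(crop.tensor[None].astype(dtype))
        p_i = float(probs["idh"][0, 1])
        p_a = float(probs["atrx"][0, 1])
        p_c = float(probs["codel_1p19q"][0, 1])
        rows.append({
            "subject_id": s.subject_id,
            "p_idh_mut": p_i, "p_atrx_mut": p_a, "p_codel": p_c,
            "pred_idh": int(p_i >= 0.5), "pred_atrx": int(p_a >= 0.5),
            "pred_codel": int(p_c >= 0.5),
        })
    return pd.DataFrame(rows)


def evaluate(model: GenotypeNet, samples: list[SubjectSample]) -> EvalReport:
    """Deterministic evaluation with per-gene Acc/AUC/Sens/Spec."""
    preds = predict(model, samples)
    labels = np.stack([s.labels.as_array() for s in samples])
    score_cols = {"idh": "p_idh_mut", "atrx": "p_atrx_mut",
                  "codel_1p19q": "p_codel"}
    pred_cols = {"idh": "pred_idh", "atrx": "pred_atrx",
                 "codel_1p19q": "pred_codel"}
    per_gene = {
        g: binary_metrics(labels[:, i], preds[score_cols[g]].to_numpy(),
                          preds[pred_cols[g]].to_numpy())
        for i, g in enumerate(GENES)
    }
    return EvalReport(per_gene=per_gene, predictions=preds)


EXPORTABLE_STAGES = ("F3", "F4", "F5", "F6", "F7", "F8", "low1", "low2",
                     "rda_mid", "rda_out", "vit_map")


def export_feature_maps(model: GenotypeNet, inp: ModelInput,
                        stages=("F3", "F4", "F6", "F7", "F8"),
                        channel: int = 0) -> dict[str, np.ndarray]:
    """Dump one channel of each named stage map for a single input."""
    for st in stages:
        if st not in EXPORTABLE_STAGES:
            raise ValueError(f"unknown stage {st!r}; choose from {EXPORTABLE_STAGES}")
    dtype = np.dtype(model.cfg.dtype).type
    with no_grad():
        out = model(Tensor(inp.tensor[None].astype(dtype)), return_features=True)
    feats = out["features"]
    return {st: np.asarray(feats[st].data[0, channel]) for st in stages}


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(result: TrainResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    state = result.model.state_dict()
    state["__log_sigma__"] = result.uncertainty.log_sigma.data
    np.savez(os.path.join(out_dir, "weights.npz"), **state)
    meta = {
        "model_cfg": {**vars(result.model_cfg),
                      "fc_widths": list(result.model_cfg.fc_widths)},
        "best_epoch": result.best_epoch,
        "priors": {g: {"counts": p.counts.tolist(),
                       "max_margin": p.max_margin, "delta": p.delta}
                   for g, p in result.priors.items()},
    }
    with open(os.path.join(out_dir, "checkpoint.json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    result.history.to_csv(os.path.join(out_dir, "history.csv"), index=False)


def load_checkpoint(ckpt_dir: str) -> tuple[GenotypeNet, MultiTaskUncertainty, dict]:
    with open(os.path.join(ckpt_dir, "checkpoint.json")) as fh:
        meta = json.load(fh)
    cfg_kwargs = dict(meta["model_cfg"])
    cfg_kwargs["fc_widths"] = tuple(cfg_kwargs["fc_widths"])
    cfg = ModelConfig(**cfg_kwargs)
    model = GenotypeNet(cfg, seed=0)
    archive = np.load(os.path.join(ckpt_dir, "weights.npz"))
    state = {k: archive[k] for k in archive.files if k != "__log_sigma__"}
    model.load_state_dict(state)
    uncertainty = MultiTaskUncertainty(dtype=np.dtype(cfg.dtype).type)
    uncertainty.log_sigma.data = archive["__log_sigma__"]
    return model, uncertainty, meta
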