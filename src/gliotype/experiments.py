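"""Self-contained study procedures used by the validation suite.

Three experiments probe the method's core claims on synthetic data:

* :func:`imbalance_comparison` — on a 9:1 two-Gaussian task with unequal
  class covariances, a linear model trained with the LMF loss is compared
  against the same model trained with unweighted cross-entropy; the readout
  is minority-class sensitivity at a fixed (matched) specificity, so the
  comparison isolates the learned discriminant direction from threshold
  placement.  The class geometry is heteroscedastic on purpose: with equal
  covariances every example weighting learns the same direction and the
  experiment could not detect mitigation at all.
* :func:`igt_ablation` — paired training runs (same cohort, same seed) of
  the full network with the inter-gene auxiliary paths enabled vs disabled,
  on rule-consistent phantom cohorts; the readout is 1p/19q sensitivity on a
  held-out cohort.
* :func:`sigma_recovery` — gradient descent on the uncertainty-weighted
  objective with frozen sub-losses must drive each sigma to its stationary
  point sqrt(2 L / 3).
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import roc_curve

from .config import CohortSpec, LossConfig, ModelConfig, TrainConfig
from .losses import ClassPriorTable, MultiTaskUncertainty, lmf_loss
from .nn import Adam, Linear, Tensor
from .synthetic import generate_cohort
from .train import evaluate, train

__all__ = ["imbalance_comparison", "igt_ablation", "sigma_recovery"]


# ---------------------------------------------------------------------------
# imbalance mitigation on a 9:1 linear task
# ---------------------------------------------------------------------------

def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


#: majority class: zero-mean, long axis oblique (45 deg) to the class-mean
#: separation; minority: mean (2, 0), tight along the separation axis.
_COV_MAJORITY = _rot(np.pi / 4) @ np.diag([3.0, 0.3]) @ _rot(np.pi / 4).T
_COV_MINORITY = np.diag([0.2, 2.0])
_MU_MINORITY = np.array([2.0, 0.0])


def _sample_task(rng: np.random.Generator, n: int, minority_frac: float):
    n1 = max(2, int(round(n * minority_frac)))
    n0 = n - n1
    x = np.vstack([
        rng.multivariate_normal([0.0, 0.0], _COV_MAJORITY, n0),
        rng.multivariate_normal(_MU_MINORITY, _COV_MINORITY, n1),
    ])
    y = np.r_[np.zeros(n0, dtype=int), np.ones(n1, dtype=int)]
    perm = rng.permutation(n)
    return x[perm], y[perm]


def _fit_linear(x, y, kind: str, seed: int, steps: int = 400) -> Linear:
    rng = np.random.default_rng(seed)
    lin = Linear(2, 2, rng)
    priors = ClassPriorTable.from_labels(y, max_margin=0.5)
    cfg = LossConfig()
    opt = Adam(lin.parameters(), lr=0.05)
    xt = Tensor(x)
    for _ in range(steps):
        logits = lin(xt)
        if kind == "lmf":
            loss = lmf_loss(logits, y, priors, cfg)
        elif kind == "ce":
            loss = (logits.logsumexp(axis=1)
                    - logits.gather(y[:, None], axis=1).reshape(-1)).mean()
        else:
            raise ValueError(f"unknown loss kind {kind!r}")
        opt.zero_grad()
        loss.backward()
        opt.step()
    return lin


def sensitivity_at_specificity(scores, y_true, specificity: float = 0.9) -> float:
    """Highest TPR attainable at >= the requested TNR, from the ROC curve."""
    fpr, tpr, _ = roc_curve(y_true, scores)
    ok = (1.0 - fpr) >= specificity
    return float(tpr[ok].max()) if ok.any() else 0.0


def imbalance_comparison(
    seed: int,
    n_train: int = 1000,
    n_test: int = 10000,
    minority_frac: float = 0.1,
    specificity: float = 0.9,
) -> dict:
    """One paired LMF-vs-CE run; returns both sensitivities at matched TNR."""
    rng = np.random.default_rng(seed)
    x_tr, y_tr = _sample_task(rng, n_train, minority_frac)
    # balanced test draw: sensitivity/specificity are per-class rates, so the
    # test mix only affects estimator variance, not the estimand
    x_te, y_te = _sample_task(rng, n_test, 0.5)
    out = {}
    for kind in ("lmf", "ce"):
        lin = _fit_linear(x_tr, y_tr, kind, seed)
        scores = lin(Tensor(x_te)).data
        out[f"sens_{kind}"] = sensitivity_at_specificity(
            scores[:, 1] - scores[:, 0], y_te, specificity
        )
    out["lmf_wins"] = bool(out["sens_lmf"] > out["sens_ce"])
    return out


# ---------------------------------------------------------------------------
# inter-gene-path ablation on phantom cohorts
# ---------------------------------------------------------------------------

_ABLATION_FRACTIONS = {"idh": 0.5, "atrx": 0.3, "codel_1p19q": 0.25}


def _ablation_spec(n: int, seed: int) -> CohortSpec:
    return CohortSpec(
        n_subjects=n, volume_shape=(24, 24, 24),
        lesion_radius_range=(3.0, 4.5), noise_sd=0.05,
        class_fractions=dict(_ABLATION_FRACTIONS), rule_adherence=1.0,
        seed=seed,
    )


def igt_ablation(
    seed: int,
    n_cohort: int = 34,
    n_val: int = 6,
    n_test: int = 36,
    epochs: int = 70,
    scale: float = 0.125,
) -> dict:
    """Paired with/without-IGT training on one rule-consistent cohort.

    Both arms share the cohort, the split and the training seed; only the
    1p/19q head wiring differs.  Returns the held-out 1p/19q sensitivity of
    each arm.
    """
    # resample (rare) draws whose training split misses a class of some gene,
    # since the margin table needs positive counts for both classes
    cohort_seed = seed
    while True:
        cohort = generate_cohort(_ablation_spec(n_cohort, cohort_seed))
        tr, va = cohort[:-n_val], cohort[-n_val:]
        labels = np.stack([s.labels.as_array() for s in tr])
        if ((labels.sum(axis=0) > 0) & (labels.sum(axis=0) < len(tr))).all():
            break
        cohort_seed += 50_000
    test = generate_cohort(_ablation_spec(n_test, 10_000 + seed))
    out = {}
    for label, use_igt in (("igt", True), ("no_igt", False)):
        mcfg = ModelConfig.scaled(scale, use_igt=use_igt)
        tcfg = TrainConfig(epochs=epochs, seed=seed, lr=1e-3, batch_size=8,
                           augment=False)
        result = train(tr, va, mcfg, tcfg)
        report = evaluate(result.model, test)
        out[f"sens_{label}"] = report.per_gene["codel_1p19q"]["sens"]
        out[f"acc_{label}"] = report.per_gene["codel_1p19q"]["acc"]
    return out


# ---------------------------------------------------------------------------
# uncertainty-weight dynamics
# ---------------------------------------------------------------------------

def sigma_recovery(
    sub_losses=(0.9, 2.4, 0.3),
    lr: float = 0.05,
    steps: int = 2000,
) -> dict:
    """Optimize the uncertainty weights against frozen sub-losses.

    The analytic stationary point per task is sigma = sqrt(2 L / 3).
    """
    mtl = MultiTaskUncertainty((5.0, 6.0, 6.0))
    losses = {g: Tensor(float(v)) for g, v in
              zip(("idh", "codel_1p19q", "atrx"), sub_losses)}
    opt = Adam(mtl.parameters(), lr=lr)
    for _ in range(steps):
        opt.zero_grad()
        mtl(losses).backward()
        opt.step()
    target = np.sqrt(2.0 * np.asarray(sub_losses, dtype=float) / 3.0)
    return {
        "sigma": mtl.sigmas,
        "target": target,
        "max_abs_error": float(np.abs(mtl.sigmas - target).max()),
    }
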