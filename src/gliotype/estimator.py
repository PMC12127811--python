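"""scikit-learn-style estimator wrapping the full genotyping pipeline."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .config import GENES, LossConfig, ModelConfig, TrainConfig
from .synthetic import GenotypeTriple, SubjectSample
from .train import evaluate as _evaluate
from .train import predict as _predict
from .train import train as _train

_PRED_COLS = {"idh": "pred_idh", "atrx": "pred_atrx", "codel_1p19q": "pred_codel"}
_PROB_COLS = {"idh": "p_idh_mut", "atrx": "p_atrx_mut", "codel_1p19q": "p_codel"}


class GliomaGenotypeClassifier(BaseEstimator, ClassifierMixin):
    """Multi-output classifier for IDH / ATRX / 1p/19q status from 4-modality MRI.

    Parameters mirror the published training recipe; ``scale`` shrinks the
    network widths and input resolution jointly (1.0 is the full-size model,
    0.125 trains on a CPU in minutes).

    Parameters
    ----------
    scale : float
        Joint width/resolution multiplier for the architecture.
    epochs, lr, weight_decay, batch_size, flip_prob : training recipe.
    alpha, beta, gamma, ldam_max_margin, ldam_delta : LMF loss settings.
    sigma_init : initial per-task uncertainty weights (idh, 1p/19q, atrx).
    use_igt : condition the 1p/19q head on the IDH/ATRX confidences.
    val_fraction : held-out fraction used for min-validation-loss selection
        when no explicit validation set is passed to :meth:`fit`.
    random_state : seed controlling initialization, split and augmentation.

    Attributes
    ----------
    model_ : the fitted network.
    uncertainty_ : fitted uncertainty-weighting module (``sigmas`` property).
    history_ : per-epoch losses, accuracies and sigma trajectory (DataFrame).
    best_epoch_ : epoch selected by minimum validation loss.
    priors_ : per-gene class-prior tables computed from the training split.
    classes_ : [0, 1] for each of the three outputs.
    """

    def __init__(self, scale: float = 0.125, epochs: int = 60, lr: float = 1e-4,
                 weight_decay: float = 1e-5, batch_size: int = 2,
                 flip_prob: float = 0.5, alpha: float = 0.5, beta: float = 0.5,
                 gamma: float = 2.0, ldam_max_margin: float = 0.5,
                 ldam_delta: float = 0.0,
                 sigma_init: tuple[float, float, float] = (5.0, 6.0, 6.0),
                 use_igt: bool = True, val_fraction: float = 0.25,
                 augment: bool = True, random_state: int = 0):
        self.scale = scale
        self.epochs = epochs
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.flip_prob = flip_prob
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.ldam_max_margin = ldam_max_margin
        self.ldam_delta = ldam_delta
        self.sigma_init = sigma_init
        self.use_igt = use_igt
        self.val_fraction = val_fraction
        self.augment = augment
        self.random_state = random_state

    # -- helpers -------------------------------------------------------------
    def _coerce_samples(self, X, y=None) -> list[SubjectSample]:
        if len(X) == 0:
            raise ValueError("empty input")
        if isinstance(X[0], SubjectSample):
            return list(X)
        X = np.asarray(X)
        if X.ndim != 5 or X.shape[1] != 4:
            raise ValueError(
                "X must be a list of SubjectSample or an (n, 4, D, H, W) array"
            )
        if y is None:
            y = np.zeros((len(X), 3), dtype=int)
        y = np.asarray(y)
        samples = []
        for i in range(len(X)):
            vols = {m: X[i, j] for j, m in enumerate(("t1", "t1ce", "t2", "flair"))}
            samples.append(SubjectSample(
                subject_id=f"sub-{i:03d}", volumes=vols,
                availability_mask=(1, 1, 1, 1),
                labels=GenotypeTriple(*map(int, y[i])),
            ))
        return samples

    def _configs(self) -> tuple[ModelConfig, TrainConfig]:
        model_cfg = ModelConfig.scaled(self.scale, use_igt=self.use_igt)
        loss_cfg = LossConfig(alpha=self.alpha, beta=self.beta, gamma=self.gamma,
                              ldam_max_margin=self.ldam_max_margin,
                              ldam_delta=self.ldam_delta,
                              sigma_init=tuple(self.sigma_init))
        train_cfg = TrainConfig(lr=self.lr, weight_decay=self.weight_decay,
                                batch_size=self.batch_size, epochs=self.epochs,
                                flip_prob=self.flip_prob, augment=self.augment,
                                seed=self.random_state, loss=loss_cfg)
        return model_cfg, train_cfg

    # -- estimator API ---------------------------------------------------------
    def fit(self, X, y=None, validation=None):
        """Fit on subjects ``X`` (SubjectSamples, or array with label matrix y)."""
        samples = self._coerce_samples(X, y)
        if validation is not None:
            if isinstance(validation, tuple):
                val_set = self._coerce_samples(*validation)
            else:
                val_set = self._coerce_samples(validation)
            train_set = samples
        else:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(samples))
            n_val = max(1, int(round(self.val_fraction * len(samples))))
            if n_val >= len(samples):
                raise ValueError("val_fraction leaves no training subjects")
            val_set = [samples[i] for i in order[:n_val]]
            train_set = [samples[i] for i in order[n_val:]]
        model_cfg, train_cfg = self._configs()
        result = _train(train_set, val_set, model_cfg, train_cfg)
        self.model_ = result.model
        self.uncertainty_ = result.uncertainty
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        self.priors_ = result.priors
        self.classes_ = [np.array([0, 1])] * 3
        self.n_features_in_ = 4
        return self

    def predict(self, X) -> np.ndarray:
        """(n, 3) hard labels in (idh, atrx, codel_1p19q) order."""
        check_is_fitted(self, "model_")
        table = _predict(self.model_, self._coerce_samples(X))
        return table[[_PRED_COLS[g] for g in GENES]].to_numpy()

    def predict_proba(self, X) -> np.ndarray:
        """(n, 3) probabilities of the positive (mutant/codeleted) class."""
        check_is_fitted(self, "model_")
        table = _predict(self.model_, self._coerce_samples(X))
        return table[[_PROB_COLS[g] for g in GENES]].to_numpy()

    def score(self, X, y=None) -> float:
        """Mean per-gene accuracy."""
        check_is_fitted(self, "model_")
        samples = self._coerce_samples(X, y)
        report = _evaluate(self.model_, samples)
        return float(np.mean([report.per_gene[g]["acc"] for g in GENES]))

    def evaluate(self, X, y=None):
        """Full per-gene Acc/AUC/Sens/Spec report."""
        check_is_fitted(self, "model_")
        return _evaluate(self.model_, self._coerce_samples(X, y))
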