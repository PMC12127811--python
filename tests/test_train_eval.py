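"""Training loop, metrics, checkpointing and feature export."""

import numpy as np
import pandas as pd
import pytest

from gliotype.config import CohortSpec, ModelConfig, TrainConfig
from gliotype.preprocess import build_model_input, center_crop
from gliotype.synthetic import GenotypeTriple, cohort_from_genotypes
from gliotype.train import (
    binary_metrics,
    evaluate,
    export_feature_maps,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)


BALANCED_GENOTYPES = [GenotypeTriple(*g) for g in
                      [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
                       (1, 0, 1), (1, 0, 1), (0, 0, 0), (1, 1, 0)]]


def small_cohort(noise_sd=0.0, seed=0):
    spec = CohortSpec(n_subjects=8, volume_shape=(24, 24, 24),
                      lesion_radius_range=(3.0, 4.5), noise_sd=noise_sd,
                      seed=seed)
    return cohort_from_genotypes(BALANCED_GENOTYPES, spec)


def quick_train(cohort, epochs=6, seed=0, **cfg_kw):
    mcfg = ModelConfig.scaled(0.125)
    kw = dict(lr=1e-3, augment=False, batch_size=8)
    kw.update(cfg_kw)
    tcfg = TrainConfig(epochs=epochs, seed=seed, **kw)
    return train(cohort, cohort, mcfg, tcfg)


class TestMetrics:
    def test_hand_computed_confusion(self):
        # TP=3, FN=1, TN=5, FP=1
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        scores = pred.astype(float)
        m = binary_metrics(y, scores, pred)
        assert m["sens"] == pytest.approx(0.75)
        assert m["spec"] == pytest.approx(5 / 6)
        assert m["acc"] == pytest.approx(0.8)
        assert (m["tp"], m["fn"], m["tn"], m["fp"]) == (3, 1, 5, 1)

    def test_perfect_separation_gives_unit_auc_and_acc(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        m = binary_metrics(y, scores, (scores > 0.5).astype(int))
        assert m["auc"] == 1.0 and m["acc"] == 1.0

    def test_random_scores_give_half_auc(self, rng):
        n = 4000
        y = rng.integers(0, 2, n)
        scores = rng.random(n)
        m = binary_metrics(y, scores, (scores > 0.5).astype(int))
        assert abs(m["auc"] - 0.5) < 0.05

    def test_auc_invariant_to_monotone_transform(self, rng):
        y = rng.integers(0, 2, 200)
        scores = rng.random(200)
        a1 = binary_metrics(y, scores, y)["auc"]
        a2 = binary_metrics(y, np.exp(5 * scores), y)["auc"]
        assert a1 == pytest.approx(a2)

    def test_single_class_auc_is_nan(self):
        m = binary_metrics(np.zeros(4), np.random.rand(4), np.zeros(4))
        assert np.isnan(m["auc"])

    def test_accuracy_identity_from_confusion(self, rng):
        y = rng.integers(0, 2, 50)
        pred = rng.integers(0, 2, 50)
        m = binary_metrics(y, pred.astype(float), pred)
        assert m["acc"] == pytest.approx((m["tp"] + m["tn"]) / 50)


class TestTrainingLoop:
    def test_history_contract_and_selection_rule(self):
        cohort = small_cohort()
        res = quick_train(cohort, epochs=5)
        assert len(res.history) <= 5
        assert res.best_epoch == int(res.history["val_loss"].idxmin())
        for col in ("train_loss", "val_loss", "sigma_idh", "sigma_1p19q",
                    "sigma_atrx"):
            assert col in res.history.columns

    def test_same_seed_reproduces_history_exactly(self):
        cohort = small_cohort()
        h1 = quick_train(cohort, epochs=4, seed=11).history
        h2 = quick_train(cohort, epochs=4, seed=11).history
        pd.testing.assert_frame_equal(h1, h2)

    def test_different_seed_changes_history(self):
        cohort = small_cohort()
        h1 = quick_train(cohort, epochs=3, seed=1).history
        h2 = quick_train(cohort, epochs=3, seed=2).history
        assert not h1["train_loss"].equals(h2["train_loss"])

    def test_sigmas_move_during_training(self):
        cohort = small_cohort()
        res = quick_train(cohort, epochs=6)
        sig0 = res.history.iloc[0][["sigma_idh", "sigma_1p19q", "sigma_atrx"]]
        assert np.allclose(sig0, [5.0, 6.0, 6.0], atol=0.05)  # near init
        sig_last = res.history.iloc[-1][["sigma_idh", "sigma_1p19q",
                                         "sigma_atrx"]]
        assert not np.allclose(sig0.to_numpy(), sig_last.to_numpy())

    def test_empty_sets_rejected(self):
        cohort = small_cohort()
        with pytest.raises(ValueError):
            train([], cohort, ModelConfig.scaled(0.125), TrainConfig(epochs=1))


class TestEvaluatePredict:
    def test_prediction_table_schema(self):
        cohort = small_cohort()
        res = quick_train(cohort, epochs=2)
        table = predict(res.model, cohort)
        assert list(table.columns) == [
            "subject_id", "p_idh_mut", "p_atrx_mut", "p_codel",
            "pred_idh", "pred_atrx", "pred_codel",
        ]
        for col in ("p_idh_mut", "p_atrx_mut", "p_codel"):
            assert table[col].between(0, 1).all()

    def test_report_consistent_with_confusion_counts(self):
        cohort = small_cohort()
        res = quick_train(cohort, epochs=2)
        rep = evaluate(res.model, cohort)
        for g, m in rep.per_gene.items():
            n = m["tp"] + m["fn"] + m["tn"] + m["fp"]
            assert n == len(cohort)
            assert m["acc"] == pytest.approx((m["tp"] + m["tn"]) / n)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        cohort = small_cohort()
        res = quick_train(cohort, epochs=2)
        save_checkpoint(res, str(tmp_path))
        model, uncertainty, meta = load_checkpoint(str(tmp_path))
        np.testing.assert_allclose(uncertainty.log_sigma.data,
                                   res.uncertainty.log_sigma.data)
        before = predict(res.model, cohort)
        after = predict(model, cohort)
        pd.testing.assert_frame_equal(before, after)
        assert meta["best_epoch"] == res.best_epoch


class TestFeatureExport:
    def test_named_stages_exported_with_expected_shapes(self):
        cohort = small_cohort()
        res = quick_train(cohort, epochs=1)
        cfg = res.model.cfg
        inp = center_crop(build_model_input(cohort[0]), cfg.input_size)
        maps = export_feature_maps(res.model, inp)
        f = cfg.feature_size
        assert set(maps) == {"F3", "F4", "F6", "F7", "F8"}
        for arr in maps.values():
            assert arr.shape == (f, f, f)
            assert np.all(np.isfinite(arr))

    def test_export_deterministic(self):
        cohort = small_cohort()
        res = quick_train(cohort, epochs=1)
        inp = center_crop(build_model_input(cohort[0]), res.model.cfg.input_size)
        a = export_feature_maps(res.model, inp, stages=("F6",))
        b = export_feature_maps(res.model, inp, stages=("F6",))
        np.testing.assert_array_equal(a["F6"], b["F6"])

    def test_unknown_stage_rejected(self):
        cohort = small_cohort()
        res = quick_train(cohort, epochs=1)
        inp = center_crop(build_model_input(cohort[0]), res.model.cfg.input_size)
        with pytest.raises(ValueError):
            export_feature_maps(res.model, inp, stages=("F99",))
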