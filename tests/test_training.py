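"""Training schedule, patient-level folds, leakage guards, CV mechanics."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from osfpnet import (
    AugmentationSpec,
    ProtocolError,
    TrainConfig,
    lr_at_epoch,
    make_folds,
    run_cross_validation,
    train_one_fold,
)
from osfpnet.training import _scaled_fold_range, predict


class TestLearningRateSchedule:
    @pytest.mark.parametrize(
        "epoch,expected",
        [(0, 1e-3), (5, 1e-3), (6, 1e-4), (11, 1e-4), (12, 1e-5), (29, 1e-7)],
    )
    def test_decay_by_10_every_6_epochs(self, epoch, expected):
        assert lr_at_epoch(TrainConfig(), epoch) == pytest.approx(expected, rel=1e-12)

    def test_closed_form_over_all_epochs(self):
        cfg = TrainConfig()
        for e in range(cfg.epochs):
            assert lr_at_epoch(cfg, e) == pytest.approx(
                cfg.lr0 / 10 ** (e // 6), rel=1e-12
            )

    def test_epoch_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr_at_epoch(TrainConfig(), 30)

    def test_batch_size_must_be_one(self):
        with pytest.raises(ValueError, match="batch_size"):
            TrainConfig(batch_size=4)


class TestMakeFolds:
    def test_reference_cohort_fold_sizes(self):
        ids = [f"S{i:04d}" for i in range(333)]
        folds = make_folds(ids, seed=1)
        assert sum(folds.sizes) == 333
        assert all(65 <= s <= 70 for s in folds.sizes)
        # disjoint cover
        assert sorted(folds.fold_of) == sorted(ids)
        assert set(folds.fold_of.values()) == {1, 2, 3, 4, 5}
        # holding out one fold trains on the rest (267 when a 66-fold is out)
        for k, size in enumerate(folds.sizes, start=1):
            assert len(folds.fold_ids(k)) == size
            assert 333 - size == len(ids) - size

    def test_k5_protocol_is_80_20(self):
        ids = [str(i) for i in range(333)]
        folds = make_folds(ids, seed=0)
        for size in folds.sizes:
            assert size / 333 == pytest.approx(0.2, abs=0.015)

    def test_five_subjects_get_singleton_folds(self):
        assert make_folds(list("abcde"), seed=0).sizes == (1, 1, 1, 1, 1)

    def test_same_seed_same_assignment(self):
        ids = [str(i) for i in range(40)]
        assert make_folds(ids, seed=9).fold_of == make_folds(ids, seed=9).fold_of
        assert make_folds(ids, seed=9).fold_of != make_folds(ids, seed=10).fold_of

    def test_scaled_range_examples(self):
        assert _scaled_fold_range(333) == (65, 70)
        assert _scaled_fold_range(5) == (1, 2)

    @pytest.mark.parametrize("n", [5, 7, 13, 40, 100, 333])
    def test_partition_valid_for_scaled_cohort_sizes(self, n):
        folds = make_folds([str(i) for i in range(n)], seed=2)
        lo, hi = _scaled_fold_range(n)
        assert sum(folds.sizes) == n
        assert all(lo <= s <= hi for s in folds.sizes)
        assert len(folds.fold_of) == n  # disjoint cover

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            make_folds(["a", "a", "b", "c", "d"], seed=0)


@pytest.fixture(scope="module")
def micro_cohort(small_cohort):
    return small_cohort


class TestTrainOneFold:
    def test_zero_epochs_leaves_model_at_init(self, micro_model_cfg, micro_cohort):
        from osfpnet import build_model

        cfg = TrainConfig(epochs=0, seed=4)
        res = train_one_fold(micro_model_cfg, micro_cohort, [], cfg)
        ref = build_model(micro_model_cfg, seed=4)
        for (w, _), (v, _) in zip(res.model.parameters(), ref.parameters()):
            np.testing.assert_array_equal(w, v)
        assert len(res.log) == 0

    def test_runs_one_step_per_subject_per_epoch(self, micro_model_cfg, micro_cohort):
        res = train_one_fold(
            micro_model_cfg, micro_cohort[:6], micro_cohort[6:], TrainConfig(epochs=2, seed=0)
        )
        assert list(res.log.columns) == ["epoch", "lr", "train_loss", "train_acc", "val_acc"]
        assert len(res.log) == 2
        assert res.best_epoch is not None and 0.0 <= res.best_val_acc <= 1.0

    def test_training_is_deterministic_given_seeds(self, micro_model_cfg, micro_cohort, rng):
        cfg = TrainConfig(epochs=2, seed=11)
        a = train_one_fold(micro_model_cfg, micro_cohort[:5], [], cfg)
        b = train_one_fold(micro_model_cfg, micro_cohort[:5], [], cfg)
        quad = micro_cohort[5].quadruple()
        np.testing.assert_array_equal(a.model.forward(quad), b.model.forward(quad))

    def test_train_val_overlap_is_protocol_error(self, micro_model_cfg, micro_cohort):
        with pytest.raises(ProtocolError, match="share subjects"):
            train_one_fold(
                micro_model_cfg, micro_cohort, micro_cohort[:1], TrainConfig(epochs=1)
            )

    def test_augmented_variant_of_val_subject_is_caught(self, micro_model_cfg, micro_cohort):
        from osfpnet import augment

        train = augment(micro_cohort[:2], AugmentationSpec(scale_factors=(1.1,), flips=()))
        with pytest.raises(ProtocolError):
            train_one_fold(micro_model_cfg, train, micro_cohort[1:2], TrainConfig(epochs=1))

    def test_training_reduces_loss_on_separable_data(self, micro_model_cfg):
        from osfpnet import CohortSpec, generate_cohort

        recs = generate_cohort(
            CohortSpec(n_subjects=8, symptomatic_fraction=0.5, effect_size=3.0,
                       transverse_size_range=(48, 56), longitudinal_height_range=(48, 52),
                       longitudinal_aspect_range=(2.5, 2.8), seed=5)
        )
        cfg = replace(micro_model_cfg, dropout_drop_p=0.0)
        res = train_one_fold(cfg, recs, [], TrainConfig(epochs=8, seed=1))
        assert res.log["train_loss"].iloc[-1] < res.log["train_loss"].iloc[0]


@pytest.fixture(scope="module")
def cv_result(micro_model_cfg, micro_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cv")
    res = run_cross_validation(
        micro_cohort, micro_model_cfg, TrainConfig(epochs=1, seed=0),
        fold_seed=3, out_dir=out,
    )
    return res, out


class TestCrossValidation:
    def test_every_subject_tested_exactly_once(self, cv_result, micro_cohort):
        res, _ = cv_result
        tested = [sid for df in res.predictions for sid in df["subject_id"]]
        assert sorted(tested) == sorted(r.subject_id for r in micro_cohort)

    def test_fold_metrics_and_mean(self, cv_result):
        res, _ = cv_result
        assert len(res.fold_metrics) == 5
        mean = res.mean_metrics
        assert 0.0 <= mean["accuracy"] <= 1.0
        accs = [m.accuracy for m in res.fold_metrics]
        assert mean["accuracy"] == pytest.approx(np.mean(accs))

    def test_per_fold_predictions_persisted(self, cv_result):
        _, out = cv_result
        files = sorted(out.glob("fold_?.csv"))
        assert len(files) == 5
        df = pd.read_csv(files[0])
        assert list(df.columns) == ["subject_id", "label", "score_symptomatic", "prediction"]

    def test_augmented_records_rejected_as_cv_input(self, micro_model_cfg, micro_cohort):
        from osfpnet import augment

        with pytest.raises(ProtocolError, match="unaugmented"):
            run_cross_validation(
                augment(micro_cohort, AugmentationSpec(scale_factors=(1.1,), flips=())),
                micro_model_cfg, TrainConfig(epochs=1),
            )

    def test_prediction_scores_are_probabilities(self, cv_result):
        res, _ = cv_result
        for df in res.predictions:
            assert ((df["score_symptomatic"] >= 0) & (df["score_symptomatic"] <= 1)).all()


def test_predict_frame_matches_argmax(micro_model_cfg, small_cohort):
    from osfpnet import build_model

    model = build_model(micro_model_cfg, seed=0)
    df = predict(model, small_cohort[:3])
    for _, row in df.iterrows():
        assert row["prediction"] in (0, 1)
        assert (row["score_symptomatic"] > 0.5) == (row["prediction"] == 1)
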