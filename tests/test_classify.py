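"""Data subdivision, augmentation, CNN training contracts, metrics."""

import numpy as np
import pandas as pd
import pytest

from craniosynth import classify as cl
from craniosynth.distmap import DistanceMap
from craniosynth.headgen import CLASSES, DEFAULT_COUNTS


def _cohort_labels(counts=None):
    counts = counts or DEFAULT_COUNTS
    labels = {}
    i = 0
    for label, n in counts.items():
        for _ in range(n):
            labels[f"s{i:04d}"] = label
            i += 1
    return labels


class TestStratifiedFolds:
    def test_full_cohort_split_sizes(self):
        plan = cl.stratified_folds(_cohort_labels(), k=4, seed=0)
        for fold in range(4):
            assert len(plan.model_ids(fold)) == 372
            assert len(plan.evaluation_ids(fold)) == 124

    def test_every_subject_in_exactly_one_evaluation_fold(self):
        labels = _cohort_labels({"control": 20, "coronal": 8, "metopic": 9, "sagittal": 15})
        plan = cl.stratified_folds(labels, k=4, seed=1)
        seen = [s for f in range(4) for s in plan.evaluation_ids(f)]
        assert sorted(seen) == sorted(labels)

    def test_per_fold_class_proportions_within_one_sample(self):
        labels = _cohort_labels()
        plan = cl.stratified_folds(labels, k=4, seed=2)
        for fold in range(4):
            ev = plan.evaluation_ids(fold)
            for label, n in DEFAULT_COUNTS.items():
                got = sum(labels[s] == label for s in ev)
                assert abs(got - n / 4) <= 1

    def test_small_class_rejected_and_determinism(self):
        with pytest.raises(ValueError, match="fewer than"):
            cl.stratified_folds(_cohort_labels({"control": 8, "coronal": 3, "metopic": 8, "sagittal": 8}), k=4)
        labels = _cohort_labels({c: 8 for c in CLASSES})
        a = cl.stratified_folds(labels, k=4, seed=3)
        b = cl.stratified_folds(labels, k=4, seed=3)
        assert a.fold_of_subject == b.fold_of_subject


class TestAugment:
    def test_identity_when_all_sigmas_zero(self, rng):
        img = rng.random((28, 28))
        cfg = cl.AugmentConfig(sigma_pixel_noise=0, sigma_intensity=0, flip_probability=0, sigma_shift_px=0)
        assert np.array_equal(cl.augment_image(img, cfg, 0), img)

    def test_full_wrap_shift_is_identity(self, rng):
        img = rng.random((28, 28))
        assert np.array_equal(np.roll(np.roll(img, 28, axis=1), -28, axis=1), img)
        # the shift is circular: +W then -W returns the original image
        shifted = np.roll(img, 28, axis=1)
        assert np.array_equal(shifted, img)

    def test_shift_sigma_arithmetic_matches_20_degree_turn(self):
        cfg = cl.AugmentConfig()
        assert cfg.sigma_shift_px == pytest.approx(224 * 20 / 360, abs=0.005)
        # scaled to the native 28-px map width
        assert cfg.shift_sigma_for_width(28) == pytest.approx(28 * 20 / 360, abs=0.001)

    def test_flip_about_center_column_is_involution(self, rng):
        img = rng.random((28, 28))
        assert np.array_equal(img[:, ::-1][:, ::-1], img)

    def test_output_stays_in_unit_range(self, rng):
        img = rng.random((28, 28))
        cfg = cl.AugmentConfig(sigma_pixel_noise=0.5, sigma_intensity=0.5)
        out = cl.augment_image(img, cfg, 0)
        assert out.min() >= 0 and out.max() <= 1


class TestEvaluateClosedForms:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3, 0, 2])
        res = cl.metrics_from_predictions(y, y)
        assert res["accuracy"] == 1.0
        assert res["f1"] == 1.0

    def test_all_one_class_predictor_on_imbalanced_set(self):
        y_true = np.concatenate([np.full(56, 0), np.full(5, 1), np.full(14, 2), np.full(25, 3)])
        y_pred = np.zeros(100, dtype=int)
        res = cl.metrics_from_predictions(y_true, y_pred)
        assert res["accuracy"] == pytest.approx(0.56)
        # hand-computed contingency: F1(control) = 2*0.56/1.56, others 0
        assert res["f1"] == pytest.approx((2 * 0.56 / 1.56) / 4, abs=1e-12)

    def test_confusion_row_sums_equal_class_counts(self, rng):
        y_true = rng.integers(0, 4, 60)
        y_pred = rng.integers(0, 4, 60)
        cm = cl.metrics_from_predictions(y_true, y_pred)["confusion"]
        assert cm.shape == (4, 4)
        for k in range(4):
            assert cm[k].sum() == np.sum(y_true == k)

    def test_unknown_label_rejected(self, class_maps):
        bad = [DistanceMap(class_maps["control"][0].pixels, "lambdoid")]
        model = object()
        with pytest.raises(ValueError, match="unknown label"):
            cl.evaluate(model, bad)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cl.evaluate(object(), [])


def _toy_two_class(rng, n=30, noise=0.02):
    maps = []
    for i in range(n):
        img = np.full((28, 28), 0.3) + rng.normal(0, noise, (28, 28))
        label = CLASSES[i % 2]
        if label == CLASSES[0]:
            img[:, :10] += 0.3  # pattern at fixed rows: survives flips
            img[5:9, :] += 0.2
        else:
            img[20:24, :] += 0.2
        maps.append(DistanceMap(np.clip(img, 0, 1), label))
    return maps


class TestTrainClassifier:
    def test_linearly_separable_toy_set_reaches_perfect_f1(self, rng):
        maps = _toy_two_class(rng, n=40)
        cfg = cl.TrainConfig(
            epochs=20,
            seed=0,
            augment=cl.AugmentConfig(flip_probability=0.0, sigma_shift_px=0.0),
        )
        clf = cl.train_classifier(maps[:24], maps[24:], cfg)
        assert clf.history["val_f1"].max() == 1.0
        res = cl.evaluate(clf, maps[24:])
        assert res["f1"] == 1.0

    def test_learning_rate_schedule_from_history(self, rng):
        maps = _toy_two_class(rng, n=24)
        cfg = cl.TrainConfig(epochs=12, learning_rate=1e-4, seed=1)
        clf = cl.train_classifier(maps[:16], maps[16:], cfg)
        lr = clf.history.set_index("epoch")["lr"]
        assert lr.loc[0] == pytest.approx(1e-4)
        assert lr.loc[4] == pytest.approx(1e-4)
        assert lr.loc[5] == pytest.approx(1e-4 * 0.63)
        assert lr.loc[11] == pytest.approx(1e-4 * 0.63**2)

    def test_returned_model_reproduces_best_epoch_validation_score(self, rng):
        maps = _toy_two_class(rng, n=36, noise=0.08)
        cfg = cl.TrainConfig(epochs=10, seed=2)
        clf = cl.train_classifier(maps[:24], maps[24:], cfg)
        res = cl.evaluate(clf, maps[24:])
        assert res["f1"] == pytest.approx(clf.history["val_f1"].max(), abs=1e-12)

    def test_mismatched_class_sets_rejected(self, rng):
        maps = _toy_two_class(rng, n=20)
        only_first = [m for m in maps if m.label == CLASSES[0]]
        with pytest.raises(ValueError, match="class sets differ"):
            cl.train_classifier(maps[:10], only_first[:4], cl.TrainConfig(epochs=1))


class TestLeakageGuard:
    def test_guard_trips_on_injected_evaluation_subject(self):
        with pytest.raises(cl.LeakageError, match="leaked"):
            cl.assert_no_leakage(["a", "b", "evil"], ["evil", "z"])

    def test_guard_passes_on_disjoint_sets(self):
        cl.assert_no_leakage(["a", "b"], ["c", "d"])

    def test_source_combinations_cover_table_rows(self):
        assert len(cl.SOURCE_COMBINATIONS) == 8
        assert ("gan", "pca", "ssm") in cl.SOURCE_COMBINATIONS
        assert ("clinical",) in cl.SOURCE_COMBINATIONS

    def test_training_set_assembly_concatenates_sources(self, class_maps):
        per_source = {
            "ssm": class_maps["control"][:3],
            "pca": class_maps["control"][3:6],
            "gan": class_maps["control"][6:9],
        }
        assert len(cl.synthesize_training_images(per_source, ("ssm",))) == 3
        assert len(cl.synthesize_training_images(per_source, ("gan", "ssm"))) == 6
        assert len(cl.synthesize_training_images(per_source, ("gan", "pca", "ssm"))) == 9
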