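"""Splitting, base-learner tuning, stacking and confusion-matrix metrics."""

import numpy as np
import pandas as pd
import pytest

from ramanstage import classify
from ramanstage.classify import (
    CVSpec,
    SplitSpec,
    confusion,
    default_specs,
    evaluate,
    fit_base_learners,
    fit_stacked,
    overall_accuracy,
    predict_stacked,
    report_from_confusion,
    sensitivity,
    specificity,
    split_train_test,
    train_stacked,
)
from ramanstage.datatypes import SpectraSet
from ramanstage.pipeline import REFERENCE_CLASS_ORDER, REFERENCE_COUNTS

SMALL_CV = CVSpec(folds=3, repeats=1, seed=0)


def _labelled_set(n_per_class, n_channels=8, seed=0, sep=10.0):
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for k, cls in enumerate(("P1", "P4", "PHH")):
        mean = np.zeros(n_channels)
        mean[k] = sep
        blocks.append(rng.normal(mean, 1.0, size=(n_per_class, n_channels)))
        labels += [cls] * n_per_class
    X = np.vstack(blocks)
    axis = 300.0 + 10.0 * np.arange(n_channels)
    meta = pd.DataFrame(
        {"spectrum_id": [f"s{i:04d}" for i in range(len(labels))], "label": labels}
    )
    return SpectraSet(axis, X, meta)


class TestSplit:
    def test_unstratified_published_sizes(self):
        """1850 spectra at 75% training split into 1388 / 462."""
        labels = ["PHH"] * 620 + ["P1"] * 624 + ["P4"] * 606
        axis = np.array([300.0, 400.0, 500.0])
        rng = np.random.default_rng(0)
        s = SpectraSet(
            axis,
            rng.normal(size=(1850, 3)),
            pd.DataFrame({"spectrum_id": [f"s{i}" for i in range(1850)], "label": labels}),
        )
        train, test = split_train_test(s, SplitSpec(stratified=False, seed=1))
        assert (len(train), len(test)) == (1388, 462)

    def test_stratified_exact_per_class_counts(self):
        s = _labelled_set(40)
        train, test = split_train_test(s, SplitSpec(seed=2))
        _, counts = np.unique(test.labels.astype(str), return_counts=True)
        assert list(counts) == [10, 10, 10]

    def test_same_seed_identical_partition(self):
        s = _labelled_set(20)
        a_train, a_test = split_train_test(s, SplitSpec(seed=3))
        b_train, b_test = split_train_test(s, SplitSpec(seed=3))
        assert list(a_test.spectrum_ids) == list(b_test.spectrum_ids)
        assert list(a_train.spectrum_ids) == list(b_train.spectrum_ids)

    def test_split_is_disjoint_and_exhaustive(self):
        s = _labelled_set(12)
        train, test = split_train_test(s, SplitSpec(seed=4))
        ids = set(train.spectrum_ids) | set(test.spectrum_ids)
        assert len(ids) == len(s)
        assert not set(train.spectrum_ids) & set(test.spectrum_ids)

    def test_unlabelled_rejected(self):
        s = _labelled_set(4)
        s.meta.loc[0, "label"] = None
        with pytest.raises(ValueError, match="labelled"):
            split_train_test(s, SplitSpec())


class TestBaseLearners:
    def test_meta_feature_layout_and_probability_rows(self):
        s = _labelled_set(12, seed=5)
        learners, meta, order = fit_base_learners(s, cv=SMALL_CV, seed=5)
        assert meta.shape == (36, 6 * 3)
        assert list(order) == ["P1", "P4", "PHH"]
        for j, kind in enumerate(classify.LEARNER_ORDER):
            block = meta[:, 3 * j: 3 * (j + 1)]
            np.testing.assert_allclose(block.sum(axis=1), 1.0, atol=1e-6)

    def test_separable_data_high_cv_accuracy_for_every_learner(self):
        s = _labelled_set(15, seed=6)
        learners, _, _ = fit_base_learners(s, cv=SMALL_CV, seed=6)
        assert set(learners) == set(classify.LEARNER_ORDER)
        for kind, tuned in learners.items():
            assert tuned.cv_accuracy > 0.95, kind

    def test_fold_count_exceeding_class_size_rejected(self):
        s = _labelled_set(4)
        with pytest.raises(ValueError, match="fold count"):
            fit_base_learners(s, cv=CVSpec(folds=5, repeats=1, seed=0))

    def test_tuning_is_deterministic(self):
        s = _labelled_set(10, seed=7, sep=2.0)
        a, meta_a, _ = fit_base_learners(s, cv=SMALL_CV, seed=7)
        b, meta_b, _ = fit_base_learners(s, cv=SMALL_CV, seed=7)
        assert {k: v.params for k, v in a.items()} == {k: v.params for k, v in b.items()}
        np.testing.assert_array_equal(meta_a, meta_b)


class TestStacked:
    def test_perfect_meta_predictor_dominates(self):
        """Stacked CV accuracy >= a perfect base learner's accuracy - 1 point."""
        rng = np.random.default_rng(8)
        y = np.repeat(["P1", "P4", "PHH"], 30)
        order = np.array(["P1", "P4", "PHH"])
        onehot = (y[:, None] == order[None, :]).astype(float)
        noise = rng.uniform(0, 1, size=(90, 3))
        noise /= noise.sum(axis=1, keepdims=True)
        meta = np.hstack([onehot, noise])
        bundle = fit_stacked(meta, y, cv=SMALL_CV, class_order=order, seed=8)
        assert bundle.meta_cv_accuracy >= 1.0 - 0.01

    def test_constant_meta_features_predict_majority_class(self):
        y = np.array(["P1"] * 10 + ["P4"] * 4 + ["PHH"] * 4)
        meta = np.full((18, 6), 0.5)
        bundle = fit_stacked(meta, y, cv=CVSpec(folds=2, repeats=1, seed=0), seed=0)
        pred = bundle.meta_learner.predict(np.full((3, 6), 0.5))
        assert set(pred) == {"P1"}

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            fit_stacked(np.zeros((5, 6)), ["a"] * 4, cv=SMALL_CV)

    def test_refit_same_seed_same_tuned_hyperparameters(self):
        s = _labelled_set(10, seed=9, sep=3.0)
        b1 = train_stacked(s, cv=SMALL_CV, seed=9)
        b2 = train_stacked(s, cv=SMALL_CV, seed=9)
        assert b1.meta_params == b2.meta_params
        assert {k: v.params for k, v in b1.base_learners.items()} == {
            k: v.params for k, v in b2.base_learners.items()
        }


@pytest.fixture(scope="module")
def trained():
    s = _labelled_set(12, seed=10)
    return s, train_stacked(s, cv=SMALL_CV, seed=10)


class TestPredict:

    def test_training_set_perfectly_predicted_when_separable(self, trained):
        s, bundle = trained
        pred = predict_stacked(bundle, s)
        assert (pred == s.labels.astype(str)).mean() == 1.0

    def test_single_spectrum_single_label(self, trained):
        s, bundle = trained
        pred = predict_stacked(bundle, s.intensities[0])
        assert pred.shape == (1,)
        assert pred[0] in set(bundle.class_order)

    def test_channel_mismatch_rejected(self, trained):
        s, bundle = trained
        with pytest.raises(ValueError, match="channels"):
            predict_stacked(bundle, s.intensities[:, :-1])

    def test_save_load_round_trip_identical_predictions(self, trained, tmp_path):
        s, bundle = trained
        classify.save_bundle(bundle, tmp_path / "model")
        loaded = classify.load_bundle(tmp_path / "model")
        np.testing.assert_array_equal(
            predict_stacked(bundle, s), predict_stacked(loaded, s)
        )
        assert list(loaded.class_order) == list(bundle.class_order)

    def test_evaluation_report_consistent_with_own_matrix(self, trained):
        s, bundle = trained
        report = evaluate(bundle, s)
        recomputed = report_from_confusion(report.confusion)
        assert recomputed.sensitivity == report.sensitivity
        assert recomputed.specificity == report.specificity
        assert recomputed.overall_accuracy == report.overall_accuracy
        assert report.n_test == len(s)


class TestSamplingLocationRobustness:
    def test_center_and_periphery_models_agree(self):
        """Models trained on center-only vs periphery-only spectra score a
        common test set within 5 percentage points (the generator encodes no
        location effect, so any gap is estimation noise)."""
        from ramanstage import preprocess, synthetic

        cfg = synthetic.SyntheticConfig(n_per_class=100, seed=41)
        dataset, _ = synthetic.generate_dataset(cfg)
        clean = preprocess.preprocess_set(dataset)
        test_cfg = synthetic.SyntheticConfig(n_per_class=40, seed=42)
        test_set = preprocess.preprocess_set(synthetic.generate_dataset(test_cfg)[0])

        accs = {}
        loc = clean.meta["location"].to_numpy()
        for location in ("center", "periphery"):
            subset = clean.subset(loc == location)
            bundle = train_stacked(subset, cv=SMALL_CV, seed=41)
            report = evaluate(bundle, test_set)
            accs[location] = report.overall_accuracy
        assert abs(accs["center"] - accs["periphery"]) < 5.0, accs


class TestConfusionMetrics:
    def _reference_matrix(self):
        return pd.DataFrame(
            REFERENCE_COUNTS,
            index=pd.Index(REFERENCE_CLASS_ORDER, name="predicted"),
            columns=pd.Index(REFERENCE_CLASS_ORDER, name="reference"),
        )

    def test_confusion_counts(self):
        pred = ["a", "a", "b", "b", "b"]
        ref = ["a", "b", "b", "b", "a"]
        m = confusion(pred, ref, ["a", "b"])
        assert m.loc["a", "a"] == 1 and m.loc["a", "b"] == 1
        assert m.loc["b", "b"] == 2 and m.loc["b", "a"] == 1

    def test_perfect_prediction_diagonal(self):
        labels = ["P1"] * 156 + ["P4"] * 151 + ["PHH"] * 155
        m = confusion(labels, labels, ["P1", "P4", "PHH"])
        assert np.trace(m.to_numpy()) == 462
        assert m.to_numpy().sum() == 462

    def test_empty_and_stray_labels_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion([], [], ["a"])
        with pytest.raises(ValueError, match="outside"):
            confusion(["a"], ["z"], ["a", "b"])

    def test_reference_matrix_metrics(self):
        """All marginal metrics follow from the printed counts."""
        m = self._reference_matrix()
        assert sensitivity(m, "P1") == 75.6
        assert sensitivity(m, "P4") == 88.7
        assert sensitivity(m, "PHH") == 89.7
        assert specificity(m, "P1") == 90.2
        assert specificity(m, "P4") == 95.5
        assert overall_accuracy(m) == 84.6

    @pytest.mark.parametrize("func", [sensitivity, specificity])
    def test_identity_matrix_metrics_100(self, func):
        m = np.eye(3, dtype=int) * 7
        assert func(m, "1") == 100.0

    def test_hand_arithmetic_2x2(self):
        m = np.array([[8, 2], [2, 8]])
        assert sensitivity(m, "1") == 80.0
        assert specificity(m, "1") == 80.0

    def test_uniform_matrix_accuracy(self):
        assert overall_accuracy(np.ones((3, 3), dtype=int)) == 33.3

    def test_single_class_specificity_undefined(self):
        m = confusion(["a", "a"], ["a", "a"], ["a"])
        assert sensitivity(m, "a") == 100.0
        with pytest.raises(ValueError, match="negatives"):
            specificity(m, "a")

    def test_zero_reference_column_rejected(self):
        m = np.array([[2, 0], [1, 0]])
        with pytest.raises(ValueError, match="reference"):
            sensitivity(m, "1")
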