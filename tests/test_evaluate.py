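import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import jittered_params
from cytosiam import (
    NetworkConfig,
    SiameseModel,
    build_gallery,
    classification_report,
    classify,
    confusion_matrix,
    metrics_from_counts,
    similarity,
)
from cytosiam.evaluate import (
    ConfusionMatrix,
    baseline_compare,
    classify_batch,
)
from cytosiam.datasets import (
    BONE_MARROW_TRAIN_COUNTS,
    BONE_MARROW_VAL_COUNTS,
    counts_to_confusion,
)


class TestMetricsFromCounts:
    def test_perfect_counts(self):
        assert metrics_from_counts(1, 1, 0, 0) == (1.0, 1.0, 1.0, 1.0)

    def test_harmonic_mean_of_equal_rates(self):
        # precision = recall = 0.5 -> F1 = 0.5
        acc, p, r, f1 = metrics_from_counts(1, 0, 1, 1)
        assert p == r == 0.5
        assert f1 == pytest.approx(0.5)

    def test_direct_plug_in(self):
        # tp=3 fp=1 fn=2 tn=4: precision 3/4, recall 3/5,
        # f1 = 2/(4/3 + 5/3) = 2/3, accuracy 7/10 — by hand
        acc, p, r, f1 = metrics_from_counts(tp=3, tn=4, fp=1, fn=2)
        assert p == pytest.approx(0.75)
        assert r == pytest.approx(0.6)
        assert f1 == pytest.approx(2 / 3, abs=1e-6)
        assert acc == pytest.approx(0.7)

    def test_zero_denominators_warn_and_return_zero(self):
        with pytest.warns(UserWarning, match="precision"):
            _, p, _, f1 = metrics_from_counts(0, 5, 0, 2)
        assert p == 0.0 and f1 == 0.0
        with pytest.warns(UserWarning, match="recall"):
            _, _, r, _ = metrics_from_counts(0, 5, 2, 0)
        assert r == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(0, 0, 0, 0)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = [0, 1, 2, 1, 0]
        cm = confusion_matrix(y, y, ["a", "b", "c"])
        assert np.trace(cm.counts) == 5
        assert cm.counts.sum() == 5

    def test_single_error_lands_in_the_right_cell(self):
        cm = confusion_matrix([0], [1], ["a", "b"])
        assert cm.counts[0, 1] == 1
        assert cm.counts.sum() == 1

    def test_row_sums_are_class_supports(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 4, 100)
        y_pred = rng.integers(0, 4, 100)
        cm = confusion_matrix(y_true, y_pred, list("abcd"))
        np.testing.assert_array_equal(
            cm.support, np.bincount(y_true, minlength=4)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0], ["a", "b"])


class TestClassificationReport:
    def test_symmetric_toy_matrix_is_all_ones(self):
        cm = ConfusionMatrix(np.array([[5, 0], [0, 5]]), ["x", "y"])
        report = classification_report(cm)
        assert report.accuracy == 1.0
        np.testing.assert_array_equal(report.precision, [1.0, 1.0])
        np.testing.assert_array_equal(report.f1, [1.0, 1.0])
        assert report.weighted_f1 == 1.0

    def test_agrees_with_the_sklearn_report(self):
        """Independent cross-check of per-class metrics and weighted
        averages against sklearn's implementation."""
        from sklearn.metrics import classification_report as sk_report

        rng = np.random.default_rng(5)
        y_true = rng.integers(0, 5, 300)
        y_pred = np.where(rng.random(300) < 0.7, y_true,
                          rng.integers(0, 5, 300))
        cm = confusion_matrix(y_true, y_pred, list("abcde"))
        ours = classification_report(cm)
        theirs = sk_report(y_true, y_pred, output_dict=True,
                           zero_division=0)
        for i, name in enumerate("abcde"):
            assert ours.precision[i] == pytest.approx(
                theirs[str(i)]["precision"])
            assert ours.recall[i] == pytest.approx(theirs[str(i)]["recall"])
            assert ours.f1[i] == pytest.approx(theirs[str(i)]["f1-score"])
        assert ours.accuracy == pytest.approx(theirs["accuracy"])
        assert ours.weighted_f1 == pytest.approx(
            theirs["weighted avg"]["f1-score"])

    def test_report_frame_has_weighted_average_row(self):
        cm = ConfusionMatrix(np.array([[3, 1], [2, 4]]), ["x", "y"])
        frame = classification_report(cm).to_frame()
        assert list(frame["class"])[-2:] == ["accuracy", "weighted average"]


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    counts=arrays(np.int64, (4, 4),
                  elements=st.integers(min_value=0, max_value=50))
)
def test_weighted_recall_equals_trace_accuracy_identity(counts):
    """Support-weighted one-vs-rest recall is mathematically identical to
    trace accuracy: sum_c (n_c/N) * (diag_c/n_c) = trace/N."""
    if counts.sum() == 0 or np.any(counts.sum(axis=1) == 0):
        return
    cm = ConfusionMatrix(counts, list("wxyz"))
    report = classification_report(cm)
    assert report.weighted_recall == pytest.approx(report.accuracy,
                                                   abs=1e-12)


class TestPublishedBenchmarkCounts:
    def test_training_split_accuracy_rounds_to_0_91(self):
        report = classification_report(
            counts_to_confusion(BONE_MARROW_TRAIN_COUNTS)
        )
        assert report.support.sum() == 109670
        assert round(report.accuracy, 2) == 0.91

    def test_validation_split_accuracy_rounds_to_0_84(self):
        report = classification_report(
            counts_to_confusion(BONE_MARROW_VAL_COUNTS)
        )
        assert report.support.sum() == 30837
        assert round(report.accuracy, 2) == 0.84


@pytest.fixture(scope="module")
def toy_model():
    cfg = NetworkConfig(input_size=16, conv_channels=(2, 4),
                        encoding_dim=8, dense_widths=(8, 6, 4, 3, 1))
    return SiameseModel(params=jittered_params(cfg, 13), config=cfg)


class TestSimilarityAndGallery:
    def test_similarity_bounded_in_percent(self, toy_model, small_dataset):
        v = similarity(toy_model, small_dataset.images[0],
                       small_dataset.images[1])
        assert 0.0 <= v <= 100.0

    def test_zero_weight_model_gives_constant_similarity(self,
                                                         small_dataset):
        cfg = NetworkConfig(input_size=16, conv_channels=(2,),
                            encoding_dim=4, dense_widths=(4, 3, 3, 2, 1))
        from cytosiam import init_params

        params = init_params(cfg, 0)
        for name, arr in params.named_arrays():
            if name.endswith("weight") or name.endswith("kernel"):
                arr[...] = 0.0
        params.head_biases[-1][...] = 0.3
        model = SiameseModel(params, cfg)
        expected = 100.0 / (1.0 + np.exp(-0.3))
        for i in range(3):
            assert similarity(
                model, small_dataset.images[i], small_dataset.images[i + 1]
            ) == pytest.approx(expected)

    def test_gallery_shape_and_determinism(self, toy_model, small_dataset):
        g1 = build_gallery(toy_model, small_dataset, k_per_class=5, seed=1)
        g2 = build_gallery(toy_model, small_dataset, k_per_class=5, seed=1)
        assert g1.n_classes == 3
        assert sum(e.shape[0] for e in g1.encodings) == 15
        for a, b in zip(g1.encodings, g2.encodings):
            np.testing.assert_array_equal(a, b)

    def test_gallery_encodings_match_their_sources(self, toy_model,
                                                   small_dataset):
        g = build_gallery(toy_model, small_dataset, k_per_class=3, seed=2)
        for c in range(g.n_classes):
            direct = toy_model.encode(
                small_dataset.images[g.source_indices[c]]
            )
            np.testing.assert_array_equal(g.encodings[c], direct)

    def test_single_class_gallery_always_wins(self, toy_model,
                                              small_dataset):
        only = small_dataset.subset(
            np.flatnonzero(small_dataset.labels == 1)
        )
        # keep the full label set but only class 1 has examples: build a
        # gallery from the one-class subset directly
        from cytosiam.evaluate import Gallery

        enc = toy_model.encode(only.images[:2])
        gallery = Gallery(encodings=[enc], source_indices=[np.arange(2)],
                          label_names=["B"], k_per_class=2)
        label, score = classify(toy_model, gallery, small_dataset.images[0])
        assert label == 0
        assert 0.0 <= score <= 1.0

    def test_classify_is_invariant_to_gallery_ordering(self, toy_model,
                                                       small_dataset):
        g = build_gallery(toy_model, small_dataset, k_per_class=4, seed=3)
        labels_before, _ = classify_batch(toy_model, g,
                                          small_dataset.images[:6])
        for c in range(g.n_classes):
            perm = np.random.default_rng(c).permutation(
                g.encodings[c].shape[0]
            )
            g.encodings[c] = g.encodings[c][perm]
        labels_after, _ = classify_batch(toy_model, g,
                                         small_dataset.images[:6])
        np.testing.assert_array_equal(labels_before, labels_after)

    def test_empty_class_rejected(self, toy_model, small_dataset):
        subset = small_dataset.subset(
            np.flatnonzero(small_dataset.labels != 2)
        )
        with pytest.raises(ValueError, match=subset.label_names[2]):
            build_gallery(toy_model, subset, k_per_class=2, seed=0)


class TestBaselines:
    def test_both_baselines_produce_full_reports(self, toy_model,
                                                 imbalanced_dataset):
        from cytosiam import stratified_split

        tr, va = stratified_split(imbalanced_dataset, 0.25, seed=1)
        for kind in ("max_margin", "gradient_boosting"):
            report, cm = baseline_compare(tr, va, toy_model, kind, seed=0)
            assert len(report.precision) == imbalanced_dataset.n_classes
            assert cm.counts.sum() == len(va)

    def test_raw_pixel_flag(self, toy_model, imbalanced_dataset):
        from cytosiam import stratified_split

        tr, va = stratified_split(imbalanced_dataset, 0.25, seed=1)
        report, _ = baseline_compare(tr, va, toy_model, "max_margin",
                                     use_raw_pixels=True, seed=0)
        assert 0.0 <= report.accuracy <= 1.0

    def test_unknown_kind_rejected(self, toy_model, imbalanced_dataset):
        from cytosiam import stratified_split

        tr, va = stratified_split(imbalanced_dataset, 0.25, seed=1)
        with pytest.raises(ValueError, match="unknown baseline"):
            baseline_compare(tr, va, toy_model, "nearest-centroid")

    def test_single_class_input_fails_cleanly_in_pairing(self):
        """The pipeline's precondition propagates: one-class data cannot
        form dissimilar pairs."""
        from cytosiam import LabeledDataset, build_balanced_pairs

        ds = LabeledDataset(np.zeros((5, 8, 8, 3)), np.zeros(5, dtype=int),
                            ["only"])
        with pytest.raises(ValueError, match="two populated classes"):
            build_balanced_pairs(ds, 4, seed=0)
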