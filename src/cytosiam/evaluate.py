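"""Pairwise similarity scoring, gallery-based multiclass inference, and
confusion-matrix metric reports, plus classical baselines for comparison.

The pairwise model never predicts a class directly; multiclass decisions
compare a query against a gallery of per-class reference encodings and
take the class with the highest mean (symmetrised) head similarity.
Metrics follow the standard one-vs-rest TP/TN/FP/FN definitions:
accuracy (TP+TN)/(TP+TN+FP+FN), precision TP/(TP+FP), recall TP/(TP+FN)
and F1 as the harmonic mean of precision and recall, with per-class rows
aggregated into support-weighted averages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .network import SiameseModel, _head_forward
from .optim import derive_seed

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# pairwise similarity and gallery inference
# --------------------------------------------------------------------------

def similarity(model: SiameseModel, image_a, image_b) -> float:
    """Similarity percentage in [0, 100] for one image pair.

    100 * g on the two encodings; because the concatenation head is not
    structurally symmetric, both orderings are scored and averaged.
    """
    h1 = model.encode(np.asarray(image_a))
    h2 = model.encode(np.asarray(image_b))
    return 100.0 * model.pair_probability(h1, h2)


@dataclass
class Gallery:
    """Per-class reference encodings used for multiclass decisions."""

    encodings: list              # per class, array (k, encoding_dim)
    source_indices: list         # per class, array (k,) into the dataset
    label_names: list
    k_per_class: int

    @property
    def n_classes(self) -> int:
        return len(self.encodings)


def build_gallery(model: SiameseModel, dataset, k_per_class: int = 10,
                  seed: int = 0) -> Gallery:
    """Sample ``k_per_class`` reference encodings per class (with
    replacement when a class is smaller than k)."""
    if k_per_class < 1:
        raise ValueError("k_per_class must be positive")
    rng = np.random.default_rng(seed)
    encodings, sources = [], []
    for c in range(dataset.n_classes):
        idx = np.flatnonzero(dataset.labels == c)
        if len(idx) == 0:
            raise ValueError(
                f"class {dataset.label_names[c]!r} has no examples to "
                "build gallery references from"
            )
        chosen = rng.choice(idx, size=k_per_class,
                            replace=len(idx) < k_per_class)
        encodings.append(model.encode(dataset.images[chosen]))
        sources.append(np.asarray(chosen))
    return Gallery(
        encodings=encodings,
        source_indices=sources,
        label_names=list(dataset.label_names),
        k_per_class=k_per_class,
    )


def _class_scores(model: SiameseModel, gallery: Gallery,
                  h: np.ndarray) -> np.ndarray:
    """Mean symmetrised head similarity of queries ``h`` (n, E) against
    each gallery class; returns (n, C)."""
    n = h.shape[0]
    scores = np.empty((n, gallery.n_classes))
    for c, refs in enumerate(gallery.encodings):
        k = refs.shape[0]
        hq = np.repeat(h, k, axis=0)
        hr = np.tile(refs, (n, 1))
        g_ab, _ = _head_forward(hq, hr, model.params,
                                model.config.head_mode)
        g_ba, _ = _head_forward(hr, hq, model.params,
                                model.config.head_mode)
        scores[:, c] = 0.5 * (g_ab + g_ba).reshape(n, k).mean(axis=1)
    return scores


def classify(model: SiameseModel, gallery: Gallery, image):
    """Predict (label, score) for one image; the score is the winning
    class's mean similarity.  Ties break to the lowest class index."""
    labels, scores = classify_batch(model, gallery,
                                    np.asarray(image)[None])
    return int(labels[0]), float(scores[0])


def classify_batch(model: SiameseModel, gallery: Gallery, images):
    """Vectorised gallery classification of an image batch."""
    h = model.encode(np.asarray(images))
    scores = _class_scores(model, gallery, h)
    # argmax already breaks ties toward the lowest index; log them
    best = scores.max(axis=1, keepdims=True)
    ties = (scores == best).sum(axis=1) > 1
    if np.any(ties):
        logger.warning(
            "%d queries tied between classes; lowest class index chosen",
            int(ties.sum()),
        )
    labels = scores.argmax(axis=1)
    return labels, scores[np.arange(len(labels)), labels]


# --------------------------------------------------------------------------
# confusion matrices and metric reports
# --------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """C x C counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    label_names: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or \
                self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.label_names) != self.counts.shape[0]:
            raise ValueError("one label name per class is required")

    @property
    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.label_names,
                            columns=self.label_names)


def confusion_matrix(y_true, y_pred, label_names) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n = len(label_names)
    if len(y_true) and (y_true.max() >= n or y_pred.max() >= n
                        or y_true.min() < 0 or y_pred.min() < 0):
        raise ValueError("labels outside the label_names range")
    counts = _sk_confusion_matrix(y_true, y_pred, labels=np.arange(n))
    return ConfusionMatrix(counts=counts, label_names=list(label_names))


def metrics_from_counts(tp: int, tn: int, fp: int, fn: int):
    """(accuracy, precision, recall, f1) from one-vs-rest counts.

    A zero denominator in precision or recall yields 0 with a warning;
    F1 is the harmonic mean, 0 when precision + recall is 0.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("at least one count must be positive")
    accuracy = (tp + tn) / total
    if tp + fp == 0:
        warnings.warn("precision denominator is zero; reporting 0",
                      stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("recall denominator is zero; reporting 0",
                      stacklevel=2)
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else \
        2.0 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f1


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1/support with overall accuracy and
    support-weighted averages."""

    label_names: list
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float

    @property
    def weighted_precision(self) -> float:
        return float(np.average(self.precision, weights=self.support))

    @property
    def weighted_recall(self) -> float:
        return float(np.average(self.recall, weights=self.support))

    @property
    def weighted_f1(self) -> float:
        return float(np.average(self.f1, weights=self.support))

    def to_frame(self, decimals: int | None = 2) -> pd.DataFrame:
        """Tabular report; rounded to 2 decimals by default, raw values
        with ``decimals=None``."""
        rows = [
            (name, p, r, f, int(s))
            for name, p, r, f, s in zip(
                self.label_names, self.precision, self.recall,
                self.f1, self.support,
            )
        ]
        rows.append(("accuracy", np.nan, np.nan, self.accuracy,
                     int(self.support.sum())))
        rows.append(
            ("weighted average", self.weighted_precision,
             self.weighted_recall, self.weighted_f1,
             int(self.support.sum()))
        )
        frame = pd.DataFrame(
            rows, columns=["class", "precision", "recall", "f1", "support"]
        )
        if decimals is not None:
            for col in ("precision", "recall", "f1"):
                frame[col] = frame[col].round(decimals)
        return frame

    def to_dict(self) -> dict:
        return {
            "classes": {
                name: {
                    "precision": float(p),
                    "recall": float(r),
                    "f1": float(f),
                    "support": int(s),
                }
                for name, p, r, f, s in zip(
                    self.label_names, self.precision, self.recall,
                    self.f1, self.support,
                )
            },
            "accuracy": float(self.accuracy),
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
        }


def classification_report(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class one-vs-rest metrics and support-weighted averages.

    Note the identity: because per-class recall is diag/rowsum, the
    support-weighted mean recall equals the overall trace accuracy.
    """
    counts = cm.counts
    if counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    n = counts.shape[0]
    precision = np.zeros(n)
    recall = np.zeros(n)
    f1 = np.zeros(n)
    total = counts.sum()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-support classes report 0
        for c in range(n):
            tp = counts[c, c]
            fp = counts[:, c].sum() - tp
            fn = counts[c, :].sum() - tp
            tn = total - tp - fp - fn
            _, precision[c], recall[c], f1[c] = metrics_from_counts(
                int(tp), int(tn), int(fp), int(fn)
            )
    return MetricsReport(
        label_names=list(cm.label_names),
        precision=precision,
        recall=recall,
        f1=f1,
        support=cm.support.astype(np.int64),
        accuracy=float(np.trace(counts) / total),
    )


def evaluate_model(model: SiameseModel, gallery: Gallery, dataset):
    """Classify a labeled dataset against the gallery and report."""
    y_pred, _ = classify_batch(model, gallery, dataset.images)
    cm = confusion_matrix(dataset.labels, y_pred, dataset.label_names)
    return classification_report(cm), cm


# --------------------------------------------------------------------------
# baseline comparators
# --------------------------------------------------------------------------

BASELINE_KINDS = {
    "max_margin": "support-vector classifier on embeddings",
    "gradient_boosting": "gradient-boosted trees on embeddings",
}


def baseline_compare(train_set, val_set, model: SiameseModel,
                     baseline_kind: str, use_raw_pixels: bool = False,
                     seed: int = 0):
    """Train a classical multiclass baseline and report like the twins.

    Features are the trained encoder's embeddings by default (raw
    flattened pixels with ``use_raw_pixels``); the classifier is either
    a max-margin SVM or gradient-boosted trees.  Returns
    ``(MetricsReport, ConfusionMatrix)`` on the validation set.
    """
    if baseline_kind not in BASELINE_KINDS:
        raise ValueError(
            f"unknown baseline kind {baseline_kind!r}; expected one of "
            f"{sorted(BASELINE_KINDS)}"
        )
    if use_raw_pixels:
        x_train = train_set.images.reshape(len(train_set), -1)
        x_val = val_set.images.reshape(len(val_set), -1)
    else:
        x_train = model.encode(train_set.images)
        x_val = model.encode(val_set.images)
    if baseline_kind == "max_margin":
        from sklearn.svm import SVC

        clf = SVC(kernel="rbf", C=1.0,
                  random_state=derive_seed(seed, 101))
    else:
        from xgboost import XGBClassifier

        clf = XGBClassifier(
            n_estimators=100, max_depth=4, learning_rate=0.3,
            random_state=derive_seed(seed, 102), verbosity=0,
        )
    clf.fit(x_train, train_set.labels)
    y_pred = np.asarray(clf.predict(x_val), dtype=np.int64)
    cm = confusion_matrix(val_set.labels, y_pred, val_set.label_names)
    return classification_report(cm), cm
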