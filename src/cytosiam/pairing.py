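"""Class-balanced pair and triplet construction, and mini-batch iteration.

The countermeasure to class imbalance: every class contributes exactly as
many similar (same-class) as dissimilar (cross-class) pairs, with the
dissimilar partner's class drawn uniformly over the other classes rather
than proportionally to class frequency, so rare classes are seen as often
as common ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairExample:
    """Two dataset indices plus the similarity label s (1 = same class)."""

    index_a: int
    index_b: int
    s: int

    def __post_init__(self):
        if self.index_a == self.index_b:
            raise ValueError("a pair may not join an image with itself")
        if self.s not in (0, 1):
            raise ValueError("s must be 0 or 1")


@dataclass(frozen=True)
class TripletExample:
    """Anchor, same-class positive and different-class negative indices."""

    anchor: int
    positive: int
    negative: int


def _class_indices(dataset):
    return {
        c: np.flatnonzero(dataset.labels == c)
        for c in range(dataset.n_classes)
        if np.any(dataset.labels == c)
    }


def _sample_distinct(rng, idx):
    """Unordered distinct index pair from ``idx`` (len >= 2)."""
    a, b = rng.choice(idx, size=2, replace=False)
    return int(a), int(b)


def build_balanced_pairs(dataset, pairs_per_class: int, seed: int = 0):
    """Emit ``pairs_per_class`` similar and dissimilar pairs per class.

    Classes with a single example are skipped entirely (their one image
    can still appear as a dissimilar partner of other classes) so the
    per-class similar/dissimilar balance holds for every class that
    contributes pairs at all.  Sampling is with replacement across
    pairs, so small classes simply reuse their members.
    """
    if pairs_per_class < 1:
        raise ValueError("pairs_per_class must be positive")
    by_class = _class_indices(dataset)
    if len(by_class) < 2:
        raise ValueError(
            "at least two populated classes are required to form "
            "dissimilar pairs"
        )
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    pairs = []
    for c in sorted(by_class):
        idx = by_class[c]
        if len(idx) < 2:
            logger.warning(
                "class %s has one example; skipped for pair generation",
                dataset.label_names[c],
            )
            continue
        others = [k for k in sorted(by_class) if k != c]
        for _ in range(pairs_per_class):
            a, b = _sample_distinct(rng, idx)
            pairs.append(PairExample(a, b, 1))
        for _ in range(pairs_per_class):
            a = int(rng.choice(idx))
            k = others[int(rng.integers(len(others)))]
            b = int(rng.choice(by_class[k]))
            pairs.append(PairExample(a, b, 0))
    for p in pairs:  # invariant: s is the same-class indicator
        assert p.s == int(labels[p.index_a] == labels[p.index_b])
    return pairs


def build_triplets(dataset, n_per_class: int, seed: int = 0):
    """Anchor/positive/negative index triplets, ``n_per_class`` per
    eligible (>= 2 member) anchor class."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be positive")
    by_class = _class_indices(dataset)
    if len(by_class) < 2:
        raise ValueError("at least two populated classes are required")
    rng = np.random.default_rng(seed)
    triplets = []
    for c in sorted(by_class):
        idx = by_class[c]
        if len(idx) < 2:
            logger.warning(
                "class %s has one example; contributes no triplets",
                dataset.label_names[c],
            )
            continue
        others = [k for k in sorted(by_class) if k != c]
        for _ in range(n_per_class):
            a, p = _sample_distinct(rng, idx)
            k = others[int(rng.integers(len(others)))]
            n = int(rng.choice(by_class[k]))
            triplets.append(TripletExample(a, p, n))
    return triplets


def minibatches(examples, batch_size: int, shuffle: bool = True,
                seed: int = 0, epoch: int = 0):
    """Partition ``examples`` into batches; the final batch may be short.

    The shuffle order is a deterministic function of (seed, epoch), so
    resumed training replays the same order.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    examples = list(examples)
    if not examples:
        return []
    order = np.arange(len(examples))
    if shuffle:
        np.random.default_rng([seed, epoch]).shuffle(order)
    return [
        [examples[i] for i in order[start:start + batch_size]]
        for start in range(0, len(examples), batch_size)
    ]


def pairs_to_frame(pairs) -> pd.DataFrame:
    """Pair list as a DataFrame with columns index_a, index_b, s."""
    return pd.DataFrame(
        [(p.index_a, p.index_b, p.s) for p in pairs],
        columns=["index_a", "index_b", "s"],
    )


def pairs_from_frame(frame: pd.DataFrame):
    return [
        PairExample(int(r.index_a), int(r.index_b), int(r.s))
        for r in frame.itertuples(index=False)
    ]
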