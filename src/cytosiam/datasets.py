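"""Bundled reference tables for the 21-class bone-marrow benchmark.

The public bone-marrow cytology benchmark (945 patients, >170,000
May-Grünwald-Giemsa-stained single-cell crops, 21 morphologic classes)
comes with published per-class correct-classification counts for a
similarity-learning classifier on its 109,670-image training split and
30,837-image validation split.  Those counts are reproduced here so the
metrics engine can be exercised on real published numbers without
downloading any image data: arranged on the diagonal of a confusion
matrix they determine the overall accuracy exactly.
"""

from __future__ import annotations

import numpy as np

from .evaluate import ConfusionMatrix

#: Class order in which the published counts are listed.
BONE_MARROW_COUNT_ORDER = (
    "LYI", "PEB", "FGC", "MYB", "OTH", "BLA", "MMZ", "MON", "ART", "BAS",
    "PMO", "EOS", "KSC", "ABE", "PLM", "NGB", "HAC", "EBO", "NIF", "LYT",
    "NGS",
)

#: Published per-class (correctly classified, total) counts on the
#: 109,670-image training split.
BONE_MARROW_TRAIN_COUNTS = {
    "LYI": (41, 41),
    "PEB": (1752, 1753),
    "FGC": (30, 30),
    "MYB": (4182, 4196),
    "OTH": (188, 188),
    "BLA": (7576, 7662),
    "MMZ": (1943, 1955),
    "MON": (2579, 2585),
    "ART": (4931, 12563),
    "BAS": (282, 282),
    "PMO": (7480, 7676),
    "EOS": (3765, 3765),
    "KSC": (26, 26),
    "ABE": (5, 5),
    "PLM": (4865, 4882),
    "NGB": (6315, 6379),
    "HAC": (261, 261),
    "EBO": (17070, 17532),
    "NIF": (2260, 2264),
    "LYT": (15971, 16794),
    "NGS": (18183, 18831),
}

#: Published per-class (correctly classified, total) counts on the
#: 30,837-image validation split.
BONE_MARROW_VAL_COUNTS = {
    "LYI": (10, 11),
    "PEB": (414, 493),
    "FGC": (2, 8),
    "MYB": (1050, 1180),
    "OTH": (11, 52),
    "BLA": (1928, 2155),
    "MMZ": (445, 549),
    "MON": (356, 727),
    "ART": (3264, 3533),
    "BAS": (28, 79),
    "PMO": (2008, 2158),
    "EOS": (986, 1058),
    "KSC": (7, 7),
    "ABE": (1, 1),
    "PLM": (1282, 1373),
    "NGB": (1530, 1794),
    "HAC": (56, 73),
    "EBO": (4062, 4931),
    "NIF": (524, 636),
    "LYT": (2912, 4723),
    "NGS": (5136, 5296),
}


def counts_to_confusion(counts: dict) -> ConfusionMatrix:
    """Arrange per-class (correct, total) counts as a confusion matrix.

    The correct count of each class sits on the diagonal; the published
    counts do not say where misclassifications went, so each row's
    remainder is placed in a single off-diagonal cell (the next class,
    cyclically).  Overall accuracy depends only on the diagonal and the
    row totals, so this arbitrary placement does not affect it.
    """
    names = list(BONE_MARROW_COUNT_ORDER)
    n = len(names)
    grid = np.zeros((n, n), dtype=np.int64)
    for i, name in enumerate(names):
        correct, total = counts[name]
        if not 0 <= correct <= total:
            raise ValueError(f"bad counts for class {name}")
        grid[i, i] = correct
        if total > correct:
            grid[i, (i + 1) % n] = total - correct
    return ConfusionMatrix(counts=grid, label_names=names)
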