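"""The standard class-imbalance benchmark on synthetic cell images.

Six classes with counts 400/200/100/50/20/10 — a 40:1 skew whose rarest
class keeps only 8 training images after the stratified 80/20 split —
rendered at 32x32 with a reduced-width encoder so a full train/evaluate/
baseline cycle runs in well under a minute per seed on one CPU.  The
same conditions back the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .evaluate import baseline_compare, build_gallery, evaluate_model
from .network import NetworkConfig, SiameseModel
from .optim import AdamHyper, derive_seed, train
from .synthgen import generate_dataset, make_phenotype_library, \
    stratified_split

BENCHMARK_CLASS_COUNTS = (400, 200, 100, 50, 20, 10)
BENCHMARK_IMAGE_SIZE = 32
BENCHMARK_SEPARATION = 0.8
BENCHMARK_VAL_FRACTION = 0.2
BENCHMARK_EPOCHS = 18
BENCHMARK_PAIRS_PER_CLASS = 40


def benchmark_config() -> NetworkConfig:
    return NetworkConfig(
        input_size=BENCHMARK_IMAGE_SIZE,
        conv_channels=(6, 12, 24),
        encoding_dim=32,
        dense_widths=(64, 32, 16, 8, 1),
    )


def run_imbalance_benchmark(seed: int, with_baselines: bool = True) -> dict:
    """Train and evaluate the twins (and optionally the baselines) on
    the standard imbalanced synthetic dataset for one root seed.

    Returns a dict with the validation accuracy, the rarest class's
    recall and F1 for every method, and the training history tail.
    """
    lib = make_phenotype_library(
        len(BENCHMARK_CLASS_COUNTS), derive_seed(seed, 21),
        separation=BENCHMARK_SEPARATION,
    )
    dataset = generate_dataset(
        lib, BENCHMARK_CLASS_COUNTS, BENCHMARK_IMAGE_SIZE,
        derive_seed(seed, 22),
    )
    train_set, val_set = stratified_split(
        dataset, BENCHMARK_VAL_FRACTION, derive_seed(seed, 23)
    )
    config = benchmark_config()
    params, history, _ = train(
        config, train_set, val_set, AdamHyper(),
        n_epochs=BENCHMARK_EPOCHS, seed=derive_seed(seed, 24),
        pairs_per_class=BENCHMARK_PAIRS_PER_CLASS, batch_size=32,
    )
    model = SiameseModel(params=params, config=config)
    gallery = build_gallery(model, train_set, k_per_class=10,
                            seed=derive_seed(seed, 25))
    report, cm = evaluate_model(model, gallery, val_set)
    rare = int(np.argmin(val_set.class_counts()))
    out = {
        "val_accuracy": report.accuracy,
        "rare_class": val_set.label_names[rare],
        "rare_recall": float(report.recall[rare]),
        "rare_f1": float(report.f1[rare]),
        "weighted_f1": report.weighted_f1,
        "final_train_pair_accuracy":
            history.records[-1]["train_pair_accuracy"],
        "final_val_pair_accuracy":
            history.records[-1]["val_pair_accuracy"],
        "report": report,
        "confusion": cm,
    }
    if with_baselines:
        for kind in ("max_margin", "gradient_boosting"):
            b_report, _ = baseline_compare(
                train_set, val_set, model, kind, seed=derive_seed(seed, 26)
            )
            out[f"{kind}_val_accuracy"] = b_report.accuracy
            out[f"{kind}_rare_f1"] = float(b_report.f1[rare])
    return out
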