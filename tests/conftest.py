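import numpy as np
import pytest

from cytosiam import (
    NetworkConfig,
    generate_dataset,
    init_params,
    make_phenotype_library,
)


@pytest.fixture(scope="session")
def tiny_config():
    """One conv stage on 8x8 inputs; small enough for finite differences."""
    return NetworkConfig(
        input_size=8, conv_channels=(1,), encoding_dim=4,
        dense_widths=(8, 6, 4, 3, 1),
    )


@pytest.fixture(scope="session")
def dense_config():
    """Conv-free configuration for the closed-form reference path."""
    return NetworkConfig(
        input_size=6, conv_channels=(), encoding_dim=5,
        dense_widths=(7, 5, 4, 3, 1),
    )


def jittered_params(config, seed):
    """He-initialised parameters with small Gaussian jitter on every
    tensor so no ReLU pre-activation sits exactly on its kink (zero
    biases otherwise put finite differences astride the kink)."""
    params = init_params(config, seed)
    rng = np.random.default_rng(seed + 1)
    for _, arr in params.named_arrays():
        arr += rng.normal(0.0, 0.05, arr.shape)
    return params


@pytest.fixture(scope="session")
def small_dataset():
    """Three well-separated classes, 16x16, modest counts."""
    lib = make_phenotype_library(3, seed=11, separation=0.8)
    return generate_dataset(lib, [12, 8, 5], image_size=16, seed=12)


@pytest.fixture(scope="session")
def imbalanced_dataset():
    """Five classes with a strong skew including a rare class."""
    lib = make_phenotype_library(5, seed=3, separation=0.8)
    return generate_dataset(lib, [40, 20, 10, 6, 2], image_size=16, seed=4)
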