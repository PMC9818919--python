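import numpy as np
import pytest

from conftest import jittered_params
from cytosiam import (
    AdamHyper,
    AdamState,
    NetworkConfig,
    adam_step,
    init_params,
    make_phenotype_library,
    generate_dataset,
    stratified_split,
    train,
)
from cytosiam.losses import GradientSet


def _scalar_setup(value=0.0):
    """A one-parameter 'network' abuse: drive adam_step through a params
    object holding a single bias tensor via a conv-free tiny config."""
    cfg = NetworkConfig(input_size=4, conv_channels=(), encoding_dim=1,
                        dense_widths=(1, 1, 1, 1, 1))
    params = init_params(cfg, 0)
    for _, arr in params.named_arrays():
        arr[...] = 0.0
    params.head_biases[-1][...] = value
    return cfg, params


def _grads_with_final_bias(params, g):
    grads = GradientSet.zeros_like(params)
    grads.head_biases[-1][...] = g
    return grads


def adam_unroll_oracle(g_seq, eta, b1, b2, eps, theta0=0.0):
    """Hand-unrolled scalar Adam recursion, independent of adam_step."""
    v = s = 0.0
    theta = theta0
    for t, g in enumerate(g_seq, start=1):
        v = b1 * v + (1 - b1) * g
        s = b2 * s + (1 - b2) * g * g
        v_hat = v / (1 - b1 ** t)
        s_hat = s / (1 - b2 ** t)
        theta = theta - eta * v_hat / (np.sqrt(s_hat) + eps)
    return theta


class TestAdamStep:
    def test_first_step_magnitude_is_eta_times_sign(self):
        hyper = AdamHyper(eta=0.05)
        for g in (0.3, -2.0, 1e-4):
            cfg, params = _scalar_setup(0.0)
            state = AdamState.zeros_like(params)
            adam_step(params, _grads_with_final_bias(params, g), state,
                      hyper)
            step = float(params.head_biases[-1][0])
            expected = -hyper.eta * g / (abs(g) + hyper.adam_eps)
            assert step == pytest.approx(expected, rel=1e-12)
            assert abs(step) == pytest.approx(
                hyper.eta * abs(g) / (abs(g) + hyper.adam_eps)
            )

    def test_two_constant_gradient_steps_match_unrolled_recursion(self):
        hyper = AdamHyper(eta=0.1, beta1=0.9, beta2=0.999, adam_eps=1e-8)
        cfg, params = _scalar_setup(0.0)
        state = AdamState.zeros_like(params)
        for _ in range(2):
            adam_step(params, _grads_with_final_bias(params, 1.0), state,
                      hyper)
        oracle = adam_unroll_oracle([1.0, 1.0], 0.1, 0.9, 0.999, 1e-8)
        assert float(params.head_biases[-1][0]) == \
            pytest.approx(oracle, rel=1e-12)
        assert state.t == 2

    def test_zero_gradients_never_move_parameters(self, tiny_config):
        params = jittered_params(tiny_config, 0)
        before = params.copy()
        state = AdamState.zeros_like(params)
        for _ in range(5):
            adam_step(params, GradientSet.zeros_like(params), state,
                      AdamHyper())
        for (_, a), (_, b) in zip(params.named_arrays(),
                                  before.named_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_beta_zero_reduces_to_sign_normalised_descent(self):
        hyper = AdamHyper(eta=0.2, beta1=0.0, beta2=0.0, adam_eps=1e-12)
        for g in (0.7, -0.01, 3.0):
            cfg, params = _scalar_setup(1.0)
            state = AdamState.zeros_like(params)
            adam_step(params, _grads_with_final_bias(params, g), state,
                      hyper)
            assert float(params.head_biases[-1][0]) == \
                pytest.approx(1.0 - hyper.eta * np.sign(g), rel=1e-9)

    def test_shape_mismatch_names_the_parameter(self, tiny_config):
        params = init_params(tiny_config, 0)
        grads = GradientSet.zeros_like(params)
        grads.enc_bias = np.zeros(3)
        with pytest.raises(ValueError, match="enc.bias"):
            adam_step(params, grads, AdamState.zeros_like(params),
                      AdamHyper())

    @pytest.mark.parametrize("kwargs", [
        {"eta": 0.0}, {"beta1": 1.0}, {"beta2": -0.1}, {"adam_eps": 0.0},
    ])
    def test_hyperparameter_validation(self, kwargs):
        with pytest.raises(ValueError):
            AdamHyper(**kwargs)


class TestInitParams:
    def test_deterministic(self, tiny_config):
        a = init_params(tiny_config, 9)
        b = init_params(tiny_config, 9)
        for (_, x), (_, y) in zip(a.named_arrays(), b.named_arrays()):
            np.testing.assert_array_equal(x, y)

    def test_he_scaling_of_large_fan_in_layers(self):
        cfg = NetworkConfig(input_size=32, conv_channels=(64,),
                            encoding_dim=32, dense_widths=(16, 8, 4, 2, 1))
        params = init_params(cfg, 0)
        fan_in = 3 * 9
        var = params.conv_kernels[0].var()
        assert abs(var - 2.0 / fan_in) < 0.2 * (2.0 / fan_in)
        enc_var = params.enc_weight.var()
        assert abs(enc_var - 2.0 / cfg.flat_dim) < 0.2 * (2.0 / cfg.flat_dim)

    def test_biases_start_at_zero(self, tiny_config):
        params = init_params(tiny_config, 1)
        for name, arr in params.named_arrays():
            if name.endswith("bias"):
                np.testing.assert_array_equal(arr, np.zeros_like(arr))


@pytest.fixture(scope="module")
def toy_two_class():
    lib = make_phenotype_library(2, seed=21, separation=0.9)
    ds = generate_dataset(lib, [24, 24], image_size=16, seed=22)
    return stratified_split(ds, 0.25, seed=23)


TOY_CONFIG = NetworkConfig(input_size=16, conv_channels=(4, 8),
                           encoding_dim=16, dense_widths=(16, 8, 4, 2, 1))


class TestTrainLoop:
    def test_zero_epochs_returns_initial_params(self, toy_two_class):
        tr, va = toy_two_class
        from cytosiam.optim import derive_seed

        params, history, _ = train(TOY_CONFIG, tr, va, n_epochs=0, seed=1)
        expected = init_params(TOY_CONFIG, derive_seed(1, 0))
        assert len(history) == 0
        for (_, a), (_, b) in zip(params.named_arrays(),
                                  expected.named_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_same_seed_is_bitwise_reproducible(self, toy_two_class):
        tr, va = toy_two_class
        p1, h1, _ = train(TOY_CONFIG, tr, va, n_epochs=2, seed=7,
                          pairs_per_class=8, batch_size=8)
        p2, h2, _ = train(TOY_CONFIG, tr, va, n_epochs=2, seed=7,
                          pairs_per_class=8, batch_size=8)
        assert h1.records == h2.records
        for (_, a), (_, b) in zip(p1.named_arrays(), p2.named_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_resume_equals_uninterrupted_training(self, toy_two_class):
        tr, va = toy_two_class
        full, _, _ = train(TOY_CONFIG, tr, va, n_epochs=3, seed=5,
                           pairs_per_class=8, batch_size=8)
        part, _, state = train(TOY_CONFIG, tr, va, n_epochs=2, seed=5,
                               pairs_per_class=8, batch_size=8)
        resumed, _, _ = train(TOY_CONFIG, tr, va, n_epochs=3, seed=5,
                              pairs_per_class=8, batch_size=8,
                              resume=(part, state, 2))
        for (_, a), (_, b) in zip(full.named_arrays(),
                                  resumed.named_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_converges_on_separable_two_class_set(self, toy_two_class):
        """A tiny net on two well-separated classes must reach >= 0.95
        training pair accuracy at threshold 0.5 within 30 epochs."""
        tr, va = toy_two_class
        _, history, _ = train(TOY_CONFIG, tr, va, AdamHyper(eta=3e-3),
                              n_epochs=30, seed=3,
                              pairs_per_class=32, batch_size=16)
        assert history.records[-1]["train_pair_accuracy"] >= 0.95

    def test_history_schema(self, toy_two_class):
        tr, va = toy_two_class
        _, history, _ = train(TOY_CONFIG, tr, va, n_epochs=2, seed=2,
                              pairs_per_class=4, batch_size=8)
        frame = history.to_frame()
        assert list(frame.columns) == [
            "epoch", "train_loss", "val_loss",
            "train_pair_accuracy", "val_pair_accuracy",
        ]
        assert len(frame) == 2
        assert (frame["train_loss"] >= 0).all()


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_convex_toy_head_loss_is_nonincreasing_under_adam(seed):
    """With fixed encodings and a single linear->sigmoid unit the pair
    NLL is convex; small-step adam_step must not increase it."""
    cfg = NetworkConfig(input_size=4, conv_channels=(), encoding_dim=3,
                        dense_widths=(1, 1, 1, 1, 1))
    params = init_params(cfg, 0)
    w = params.head_weights[0]   # (1, 6): logistic weights on (h1, h2)
    b = params.head_biases[0]
    w[...] = 0.0
    b[...] = 0.0
    r = np.random.default_rng(seed)
    x = r.standard_normal((40, 6))   # fixed concatenated encodings
    s = (x @ r.standard_normal(6) > 0).astype(float)
    hyper = AdamHyper(eta=5e-3)
    state = AdamState.zeros_like(params)
    losses = []
    for _ in range(40):
        z = x @ w[0] + b[0]
        g = 1.0 / (1.0 + np.exp(-z))
        losses.append(float(np.mean(
            -(s * np.log(g + 1e-12) + (1 - s) * np.log(1 - g + 1e-12))
        )))
        dz = (g - s) / len(s)
        grads = GradientSet.zeros_like(params)
        grads.head_weights[0][0, :] = x.T @ dz
        grads.head_biases[0][...] = dz.sum()
        adam_step(params, grads, state, hyper)
    assert all(later <= earlier + 1e-6
               for earlier, later in zip(losses, losses[1:]))
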