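"""Adam updates and the epoch training loop.

Adam keeps exponential moving averages of the gradient (first moment V)
and its elementwise square (second moment S), corrects both for their
zero initialisation with 1/(1 - beta^t), and scales the step by the
corrected first moment over the root of the corrected second moment.
Both twin branches contribute to one shared gradient per parameter, so
the moments are kept on the total gradient.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .losses import GradientSet, pair_nll, pair_forward, \
    pair_nll_gradients, triplet_gradients
from .network import EncoderParams, NetworkConfig
from .pairing import build_balanced_pairs, build_triplets, minibatches

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdamHyper:
    """Adam hyperparameters: step size eta, moment decays beta1/beta2,
    and the denominator stabiliser adam_eps."""

    eta: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if not (0.0 <= self.beta1 < 1.0 and 0.0 <= self.beta2 < 1.0):
            raise ValueError("beta1 and beta2 must lie in [0, 1)")
        if self.adam_eps <= 0:
            raise ValueError("adam_eps must be positive")


@dataclass
class AdamState:
    """First/second moment accumulators keyed by parameter name, plus
    the step counter t (0 before the first update)."""

    V: dict
    S: dict
    t: int = 0

    @classmethod
    def zeros_like(cls, params: EncoderParams) -> "AdamState":
        return cls(
            V={name: np.zeros_like(a) for name, a in params.named_arrays()},
            S={name: np.zeros_like(a) for name, a in params.named_arrays()},
            t=0,
        )


def adam_step(params: EncoderParams, grads: GradientSet,
              state: AdamState, hyper: AdamHyper):
    """One Adam update, in place; returns ``(params, state)``.

    V <- b1 V + (1-b1) g;  S <- b2 S + (1-b2) g*g;
    Vhat = V/(1-b1^t), Shat = S/(1-b2^t);
    theta <- theta - eta * Vhat / (sqrt(Shat) + eps).
    """
    state.t += 1
    t = state.t
    c1 = 1.0 - hyper.beta1 ** t
    c2 = 1.0 - hyper.beta2 ** t
    gmap = dict(grads.named_arrays())
    for name, theta in params.named_arrays():
        if name not in gmap:
            raise KeyError(f"gradient missing for parameter {name}")
        g = gmap[name]
        if g.shape != theta.shape:
            raise ValueError(
                f"gradient shape {g.shape} mismatches parameter "
                f"{name} of shape {theta.shape}"
            )
        V = state.V[name]
        S = state.S[name]
        V *= hyper.beta1
        V += (1.0 - hyper.beta1) * g
        S *= hyper.beta2
        S += (1.0 - hyper.beta2) * g * g
        theta -= hyper.eta * (V / c1) / (np.sqrt(S / c2) + hyper.adam_eps)
    return params, state


def init_params(config: NetworkConfig, seed: int = 0) -> EncoderParams:
    """He-scaled Gaussian initialisation (std = sqrt(2/fan_in)) for all
    weights, zero biases; deterministic per seed."""
    rng = np.random.default_rng(seed)
    k = config.kernel_size
    conv_kernels, conv_biases = [], []
    in_ch = config.in_channels
    for out_ch in config.conv_channels:
        fan_in = in_ch * k * k
        conv_kernels.append(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, k, k))
        )
        conv_biases.append(np.zeros(out_ch))
        in_ch = out_ch
    enc_weight = rng.normal(
        0.0, np.sqrt(2.0 / config.flat_dim),
        (config.encoding_dim, config.flat_dim),
    )
    enc_bias = np.zeros(config.encoding_dim)
    head_weights, head_biases = [], []
    prev = config.head_input_dim
    for w in config.dense_widths:
        head_weights.append(rng.normal(0.0, np.sqrt(2.0 / prev), (w, prev)))
        head_biases.append(np.zeros(w))
        prev = w
    params = EncoderParams(
        conv_kernels=conv_kernels,
        conv_biases=conv_biases,
        enc_weight=enc_weight,
        enc_bias=enc_bias,
        head_weights=head_weights,
        head_biases=head_biases,
    )
    params.validate(config)
    return params


@dataclass
class TrainingHistory:
    """Per-epoch mean pair loss and thresholded pair accuracy on the
    training and validation pair sets."""

    records: list = field(default_factory=list)

    def append(self, train_loss, val_loss, train_acc, val_acc):
        self.records.append(
            {
                "epoch": len(self.records),
                "train_loss": float(train_loss),
                "val_loss": float(val_loss),
                "train_pair_accuracy": float(train_acc),
                "val_pair_accuracy": float(val_acc),
            }
        )

    def __len__(self):
        return len(self.records)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.records,
            columns=["epoch", "train_loss", "val_loss",
                     "train_pair_accuracy", "val_pair_accuracy"],
        )


def derive_seed(seed: int, *stream) -> int:
    """Named substream seed below 2**31, stable in (seed, stream)."""
    ss = np.random.SeedSequence([int(seed), *[int(x) for x in stream]])
    return int(ss.generate_state(1)[0] % (2**31))


_STREAM_INIT, _STREAM_PAIRS, _STREAM_VAL_PAIRS, _STREAM_SHUFFLE, \
    _STREAM_GALLERY = range(5)


def _gather(dataset, pairs):
    a = dataset.images[[p.index_a for p in pairs]]
    b = dataset.images[[p.index_b for p in pairs]]
    s = np.array([p.s for p in pairs], dtype=np.float64)
    return a, b, s


def _pair_eval(dataset, pairs, params, config, batch_size=128):
    """Mean pair NLL and thresholded pair accuracy, forward only."""
    losses, correct = [], 0
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start:start + batch_size]
        a, b, s = _gather(dataset, chunk)
        g, _ = pair_forward(a, b, params, config)
        losses.append(pair_nll(g, s))
        correct += int(np.sum((g >= 0.5) == (s == 1.0)))
    per = np.concatenate(losses)
    return float(per.mean()), correct / len(pairs)


def train(
    config: NetworkConfig,
    train_set,
    val_set,
    hyper: AdamHyper = AdamHyper(),
    n_epochs: int = 30,
    seed: int = 0,
    pairs_per_class: int = 32,
    batch_size: int = 32,
    objective: str = "pair_nll",
    resume: tuple | None = None,
):
    """Train the twin network on balanced pairs (or triplets).

    All randomness derives from ``seed`` through named substreams
    (init / pairing / shuffling), so a given call is bitwise
    reproducible and a run resumed from ``resume=(params, adam_state,
    start_epoch)`` continues exactly as the uninterrupted run would.
    If the loss turns non-finite, training aborts and returns the last
    completed epoch's parameters.

    Returns ``(params, history, adam_state)``.
    """
    if objective not in ("pair_nll", "triplet"):
        raise ValueError("objective must be 'pair_nll' or 'triplet'")
    if resume is None:
        params = init_params(config, derive_seed(seed, _STREAM_INIT))
        state = AdamState.zeros_like(params)
        start_epoch = 0
    else:
        params, state, start_epoch = resume
        params = params.copy()
        state = copy.deepcopy(state)
    history = TrainingHistory()

    train_pairs = build_balanced_pairs(
        train_set, pairs_per_class, derive_seed(seed, _STREAM_PAIRS)
    )
    val_pairs = build_balanced_pairs(
        val_set, max(pairs_per_class // 2, 4),
        derive_seed(seed, _STREAM_VAL_PAIRS),
    )
    if objective == "triplet":
        train_triplets = build_triplets(
            train_set, pairs_per_class, derive_seed(seed, _STREAM_PAIRS)
        )

    last_good = params.copy()
    for epoch in range(start_epoch, n_epochs):
        shuffle_seed = derive_seed(seed, _STREAM_SHUFFLE)
        examples = train_pairs if objective == "pair_nll" else train_triplets
        batches = minibatches(examples, batch_size, shuffle=True,
                              seed=shuffle_seed, epoch=epoch)
        epoch_ok = True
        for batch in batches:
            try:
                if objective == "pair_nll":
                    a, b, s = _gather(train_set, batch)
                    loss, grads = pair_nll_gradients(a, b, s, params, config)
                else:
                    a = train_set.images[[t.anchor for t in batch]]
                    p = train_set.images[[t.positive for t in batch]]
                    n = train_set.images[[t.negative for t in batch]]
                    loss, grads = triplet_gradients(a, p, n, params, config)
            except FloatingPointError:
                epoch_ok = False
                break
            if not np.isfinite(loss.value):
                epoch_ok = False
                break
            adam_step(params, grads, state, hyper)
        if not epoch_ok:
            logger.error(
                "non-finite loss at epoch %d; aborting with the last "
                "completed epoch's parameters", epoch,
            )
            return last_good, history, state
        train_loss, train_acc = _pair_eval(train_set, train_pairs,
                                           params, config)
        val_loss, val_acc = _pair_eval(val_set, val_pairs, params, config)
        history.append(train_loss, val_loss, train_acc, val_acc)
        last_good = params.copy()
    return params, history, state
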