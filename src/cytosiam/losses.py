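"""Training objectives and their closed-form gradients.

Two objectives are provided:

* the pairwise Bernoulli negative log-likelihood of the similarity head's
  probability g against the binary same-class label s (the default), and
* the margin triplet loss on raw encodings,
  max(||h_a - h_p||^2 - ||h_a - h_n||^2 + margin, 0).

Gradients are derived by hand and propagated through the dense head, the
encoding projection, and the conv/pool stack of both shared-weight twin
branches.  A separate, deliberately pedestrian per-example implementation
of the delta recursions for dense-only configurations, plus a central
finite-difference checker, serve as independent verification paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    EncoderParams,
    NetworkConfig,
    _encoder_backward,
    _encoder_forward,
    _head_backward,
    _head_forward,
    _sigmoid,
)

_G_EPS = 1e-7  # probability clamp for the log terms


@dataclass
class LossValue:
    """A reduced batch loss plus its per-example terms."""

    value: float
    per_example: np.ndarray
    reduction: str = "sum"

    def __post_init__(self):
        self.per_example = np.asarray(self.per_example, dtype=np.float64)
        if not np.all(np.isfinite(self.per_example)):
            raise FloatingPointError("non-finite per-example losses")


@dataclass
class GradientSet:
    """Gradients mirroring EncoderParams, plus the branch gradients
    with respect to the two encodings."""

    conv_kernels: list
    conv_biases: list
    enc_weight: np.ndarray
    enc_bias: np.ndarray
    head_weights: list
    head_biases: list
    wrt_h1: np.ndarray | None = None
    wrt_h2: np.ndarray | None = None

    @classmethod
    def zeros_like(cls, params: EncoderParams) -> "GradientSet":
        return cls(
            conv_kernels=[np.zeros_like(k) for k in params.conv_kernels],
            conv_biases=[np.zeros_like(b) for b in params.conv_biases],
            enc_weight=np.zeros_like(params.enc_weight),
            enc_bias=np.zeros_like(params.enc_bias),
            head_weights=[np.zeros_like(w) for w in params.head_weights],
            head_biases=[np.zeros_like(b) for b in params.head_biases],
        )

    def named_arrays(self):
        for i, (k, b) in enumerate(zip(self.conv_kernels, self.conv_biases)):
            yield f"conv{i}.kernel", k
            yield f"conv{i}.bias", b
        yield "enc.weight", self.enc_weight
        yield "enc.bias", self.enc_bias
        for i, (w, b) in enumerate(zip(self.head_weights, self.head_biases)):
            yield f"head{i}.weight", w
            yield f"head{i}.bias", b

    def check_finite(self):
        for name, arr in self.named_arrays():
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite gradient in {name}")


# --------------------------------------------------------------------------
# triplet objective
# --------------------------------------------------------------------------

def triplet_loss(h_a, h_p, h_n, margin: float) -> float:
    """max(||h_a-h_p||^2 - ||h_a-h_n||^2 + margin, 0), squared Euclidean.

    The clamp keeps already-satisfied triplets from pushing the model
    further once the positive is closer than the negative by the margin.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    h_a, h_p, h_n = (np.asarray(h, dtype=np.float64) for h in (h_a, h_p, h_n))
    if not (np.all(np.isfinite(h_a)) and np.all(np.isfinite(h_p))
            and np.all(np.isfinite(h_n))):
        raise FloatingPointError("non-finite encodings")
    d_pos = np.sum((h_a - h_p) ** 2, axis=-1)
    d_neg = np.sum((h_a - h_n) ** 2, axis=-1)
    return np.maximum(d_pos - d_neg + margin, 0.0)


def batch_triplet_loss(triplets, dataset, params: EncoderParams,
                       config: NetworkConfig,
                       reduction: str = "sum") -> LossValue:
    """Triplet loss over index triplets into ``dataset``.

    Reduction is a plain sum by default; mean is available for
    learning-rate stability at varying batch sizes.
    """
    if not triplets:
        raise ValueError("batch of triplets must be non-empty")
    a = dataset.images[[t.anchor for t in triplets]]
    p = dataset.images[[t.positive for t in triplets]]
    n = dataset.images[[t.negative for t in triplets]]
    h_a, _ = _encoder_forward(a, params, config)
    h_p, _ = _encoder_forward(p, params, config)
    h_n, _ = _encoder_forward(n, params, config)
    per = triplet_loss(h_a, h_p, h_n, config.margin_triplet)
    value = float(per.sum() if reduction == "sum" else per.mean())
    return LossValue(value=value, per_example=per, reduction=reduction)


# --------------------------------------------------------------------------
# pairwise likelihood objective
# --------------------------------------------------------------------------

def pair_nll(g, s) -> np.ndarray | float:
    """Bernoulli negative log-likelihood -[s ln g + (1-s) ln(1-g)].

    Minimising this maximises the conditional likelihood of the
    similarity labels.  g is clamped to [1e-7, 1-1e-7] before the logs.
    """
    g = np.clip(np.asarray(g, dtype=np.float64), _G_EPS, 1.0 - _G_EPS)
    s = np.asarray(s, dtype=np.float64)
    out = -(s * np.log(g) + (1.0 - s) * np.log(1.0 - g))
    return float(out) if out.ndim == 0 else out


def pair_forward(images_a, images_b, params: EncoderParams,
                 config: NetworkConfig):
    """Similarity probabilities g for batches of image pairs, with the
    caches needed for a subsequent backward pass."""
    h1, cache_a = _encoder_forward(images_a, params, config)
    h2, cache_b = _encoder_forward(images_b, params, config)
    g, head_cache = _head_forward(h1, h2, params, config.head_mode)
    return g, (cache_a, cache_b, head_cache)


def pair_nll_gradients(images_a, images_b, s, params: EncoderParams,
                       config: NetworkConfig):
    """Loss and gradients of the summed pair NLL for a batch of pairs.

    The scalar chain for each pair is d(NLL)/dg = -(s-g)/(g(1-g));
    through the output sigmoid this collapses to g - s at the
    pre-activation, which then backpropagates through the head into the
    two encodings and onward through both shared-weight encoder
    branches (their contributions sum on the shared tensors).

    Returns ``(LossValue, GradientSet)``.
    """
    s = np.asarray(s, dtype=np.float64)
    if s.size == 0:
        raise ValueError("batch of pairs must be non-empty")
    g, (cache_a, cache_b, head_cache) = pair_forward(
        images_a, images_b, params, config
    )
    per = pair_nll(g, s)
    loss = LossValue(value=float(per.sum()), per_example=per)

    grads = GradientSet.zeros_like(params)
    dz_out = (g - s)[:, None]  # d(sum NLL)/d(pre-sigmoid)
    dh1, dh2 = _head_backward(dz_out, head_cache, params, grads)
    grads.wrt_h1 = dh1
    grads.wrt_h2 = dh2
    _encoder_backward(dh1, cache_a, params, grads)
    _encoder_backward(dh2, cache_b, params, grads)
    grads.check_finite()
    return loss, grads


def triplet_gradients(images_a, images_p, images_n, params: EncoderParams,
                      config: NetworkConfig):
    """Loss and gradients of the summed triplet loss for a batch.

    For active (unclamped) triplets dL/dh_a = 2(h_n - h_p),
    dL/dh_p = -2(h_a - h_p), dL/dh_n = 2(h_a - h_n); clamped triplets
    contribute nothing.  All three branches share the encoder weights.
    """
    h_a, cache_a = _encoder_forward(images_a, params, config)
    h_p, cache_p = _encoder_forward(images_p, params, config)
    h_n, cache_n = _encoder_forward(images_n, params, config)
    per = triplet_loss(h_a, h_p, h_n, config.margin_triplet)
    active = (per > 0.0)[:, None]
    loss = LossValue(value=float(per.sum()), per_example=per)

    grads = GradientSet.zeros_like(params)
    _encoder_backward(2.0 * (h_n - h_p) * active, cache_a, params, grads)
    _encoder_backward(-2.0 * (h_a - h_p) * active, cache_p, params, grads)
    _encoder_backward(2.0 * (h_a - h_n) * active, cache_n, params, grads)
    grads.check_finite()
    return loss, grads


# --------------------------------------------------------------------------
# independent verification paths
# --------------------------------------------------------------------------

def dense_reference_gradients(images_a, images_b, s, params: EncoderParams,
                              config: NetworkConfig) -> GradientSet:
    """Closed-form delta-recursion backprop for conv-free configurations.

    Written independently of the vectorised path: one pair at a time,
    explicit per-layer recursions delta^L = dL/dout * f'(z^L) and
    delta^l = (W^{l+1})^T delta^{l+1} * f'(z^l), with the two encoding
    branches handled one after the other and summed on the shared
    projection.  Exists to cross-validate the general implementation.
    """
    if params.conv_kernels:
        raise ValueError("reference path requires a conv-free configuration")
    images_a = np.asarray(images_a, dtype=np.float64)
    images_b = np.asarray(images_b, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    grads = GradientSet.zeros_like(params)
    grads.wrt_h1 = np.zeros((len(s), config.encoding_dim))
    grads.wrt_h2 = np.zeros((len(s), config.encoding_dim))

    n_head = len(params.head_weights)
    for m in range(len(s)):
        xa = images_a[m].reshape(-1)
        xb = images_b[m].reshape(-1)
        # encoder branch forwards
        za = params.enc_weight @ xa + params.enc_bias
        h1 = np.where(za > 0, za, 0.0)
        zb = params.enc_weight @ xb + params.enc_bias
        h2 = np.where(zb > 0, zb, 0.0)
        # head forward
        if config.head_mode == "concat":
            x0 = np.concatenate([h1, h2])
        else:
            x0 = np.abs(h1 - h2)
        xs, zhs = [x0], []
        for li in range(n_head):
            z = params.head_weights[li] @ xs[-1] + params.head_biases[li]
            zhs.append(z)
            if li == n_head - 1:
                xs.append(_sigmoid(z))
            else:
                xs.append(np.where(z > 0, z, 0.0))
        g = xs[-1][0]

        # head deltas: output layer delta is (g - s) since
        # -(s-g)/(g(1-g)) * sigmoid'(z) = g - s
        delta = np.array([g - s[m]])
        for li in range(n_head - 1, -1, -1):
            grads.head_weights[li] += np.outer(delta, xs[li])
            grads.head_biases[li] += delta
            if li > 0:
                delta = (params.head_weights[li].T @ delta) * \
                    (zhs[li - 1] > 0)
        dx0 = params.head_weights[0].T @ delta
        if config.head_mode == "concat":
            e = config.encoding_dim
            dh1, dh2 = dx0[:e], dx0[e:]
        else:
            sign = np.sign(h1 - h2)
            dh1, dh2 = dx0 * sign, -dx0 * sign
        grads.wrt_h1[m] = dh1
        grads.wrt_h2[m] = dh2

        # encoder branch deltas on the shared projection
        for dh, z, x in ((dh1, za, xa), (dh2, zb, xb)):
            d_enc = dh * (z > 0)
            grads.enc_weight += np.outer(d_enc, x)
            grads.enc_bias += d_enc
    return grads


def pair_nll_loss_fn(images_a, images_b, s, params, config) -> float:
    """Scalar summed pair NLL; the quantity the gradients differentiate."""
    g, _ = pair_forward(images_a, images_b, params, config)
    return float(pair_nll(g, np.asarray(s, dtype=np.float64)).sum())


def finite_difference_gradients(images_a, images_b, s,
                                params: EncoderParams,
                                config: NetworkConfig,
                                step: float = 1e-5) -> GradientSet:
    """Central finite differences of the summed pair NLL on every
    parameter entry.  O(#params) forward passes; tiny nets only."""
    grads = GradientSet.zeros_like(params)
    work = params.copy()
    for (name, arr), (_, out) in zip(work.named_arrays(),
                                     grads.named_arrays()):
        flat = arr.reshape(-1)
        gout = out.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + step
            lp = pair_nll_loss_fn(images_a, images_b, s, work, config)
            flat[i] = orig - step
            lm = pair_nll_loss_fn(images_a, images_b, s, work, config)
            flat[i] = orig
            gout[i] = (lp - lm) / (2.0 * step)
    return grads


def max_relative_gradient_error(analytic: GradientSet,
                                numeric: GradientSet) -> float:
    """Worst per-tensor max|a-n| / max(max|n|, 1e-8) across parameters."""
    worst = 0.0
    for (_, a), (_, n) in zip(analytic.named_arrays(),
                              numeric.named_arrays()):
        scale = max(float(np.max(np.abs(n))), 1e-8)
        worst = max(worst, float(np.max(np.abs(a - n))) / scale)
    return worst
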