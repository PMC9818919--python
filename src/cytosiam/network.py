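"""Twin-encoder network: conv/pool stages, flatten, dense encoding, and a
dense similarity head on the concatenated pair of encodings.

All tensors are numpy arrays, channels last (H, W, C).  Convolutions use
stride 1 with zero padding of (k-1)/2, so the spatial size is unchanged;
each 2x2 max-pool halves it with floor-and-drop for odd sizes, which for a
50x50 input gives the 25 -> 12 -> 6 -> 3 chain and a 3x3 map ahead of the
flatten.  The public single-image operations wrap batched internals that
also cache the intermediates backpropagation needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


# --------------------------------------------------------------------------
# configuration and parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``dense_widths`` are the five similarity-head layer widths, last one 1
    (the similarity unit).  ``margin_triplet`` is the margin of the triplet
    objective; it does not enter the head (the head has no use for a
    margin argument, so it is accepted by the loss API only).
    ``head_mode`` selects what the head consumes: the concatenation
    (h1, h2) or the elementwise absolute difference |h1 - h2|.
    """

    input_size: int = 50
    in_channels: int = 3
    conv_channels: tuple = (8, 16, 32, 64)
    kernel_size: int = 3
    encoding_dim: int = 64
    dense_widths: tuple = (64, 32, 16, 8, 1)
    margin_triplet: float = 0.2
    activation: str = "relu"
    head_mode: str = "concat"

    def __post_init__(self):
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValueError("kernel_size must be a positive odd integer")
        if len(self.dense_widths) != 5 or self.dense_widths[-1] != 1:
            raise ValueError("dense_widths must be 5 widths ending in 1")
        if any(w < 1 for w in self.dense_widths):
            raise ValueError("all dense widths must be >= 1")
        if not 0 <= len(self.conv_channels) <= 4:
            raise ValueError("conv_channels may list at most 4 stages")
        if any(c < 1 for c in self.conv_channels):
            raise ValueError("conv channel counts must be positive")
        if self.head_mode not in ("concat", "absdiff"):
            raise ValueError("head_mode must be 'concat' or 'absdiff'")
        if self.activation != "relu":
            raise ValueError("only relu hidden activation is supported")
        s = self.input_size
        for _ in self.conv_channels:
            s //= 2
            if s < 1:
                raise ValueError("input_size too small for the conv stack")

    @property
    def spatial_sizes(self) -> tuple:
        """Spatial size after each pooling stage, starting at input_size."""
        sizes = [self.input_size]
        for _ in self.conv_channels:
            sizes.append(sizes[-1] // 2)
        return tuple(sizes)

    @property
    def flat_dim(self) -> int:
        s = self.spatial_sizes[-1]
        c = self.conv_channels[-1] if self.conv_channels else self.in_channels
        return s * s * c

    @property
    def head_input_dim(self) -> int:
        return (2 if self.head_mode == "concat" else 1) * self.encoding_dim

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "in_channels": self.in_channels,
            "conv_channels": list(self.conv_channels),
            "kernel_size": self.kernel_size,
            "encoding_dim": self.encoding_dim,
            "dense_widths": list(self.dense_widths),
            "margin_triplet": self.margin_triplet,
            "activation": self.activation,
            "head_mode": self.head_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for k in ("conv_channels", "dense_widths"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class EncoderParams:
    """All trainable tensors: conv kernels/biases, the encoding
    projection, and the five head layers (shared across the twins)."""

    conv_kernels: list          # each (out_ch, in_ch, k, k)
    conv_biases: list           # each (out_ch,)
    enc_weight: np.ndarray      # (encoding_dim, flat_dim)
    enc_bias: np.ndarray        # (encoding_dim,)
    head_weights: list          # five (width_i, prev_width)
    head_biases: list           # five (width_i,)

    def named_arrays(self):
        """Ordered (name, array) view; Adam and checkpoints iterate this."""
        for i, (k, b) in enumerate(zip(self.conv_kernels, self.conv_biases)):
            yield f"conv{i}.kernel", k
            yield f"conv{i}.bias", b
        yield "enc.weight", self.enc_weight
        yield "enc.bias", self.enc_bias
        for i, (w, b) in enumerate(zip(self.head_weights, self.head_biases)):
            yield f"head{i}.weight", w
            yield f"head{i}.bias", b

    def copy(self) -> "EncoderParams":
        return EncoderParams(
            conv_kernels=[k.copy() for k in self.conv_kernels],
            conv_biases=[b.copy() for b in self.conv_biases],
            enc_weight=self.enc_weight.copy(),
            enc_bias=self.enc_bias.copy(),
            head_weights=[w.copy() for w in self.head_weights],
            head_biases=[b.copy() for b in self.head_biases],
        )

    def validate(self, config: NetworkConfig) -> None:
        """Raise if any tensor shape disagrees with ``config``."""
        in_ch = config.in_channels
        k = config.kernel_size
        if len(self.conv_kernels) != len(config.conv_channels):
            raise ValueError("conv stage count mismatch")
        for i, out_ch in enumerate(config.conv_channels):
            expect = (out_ch, in_ch, k, k)
            if self.conv_kernels[i].shape != expect:
                raise ValueError(
                    f"conv{i}.kernel has shape {self.conv_kernels[i].shape}, "
                    f"expected {expect}"
                )
            in_ch = out_ch
        if self.enc_weight.shape != (config.encoding_dim, config.flat_dim):
            raise ValueError(
                f"enc.weight has shape {self.enc_weight.shape}, expected "
                f"{(config.encoding_dim, config.flat_dim)}"
            )
        prev = config.head_input_dim
        for i, w in enumerate(config.dense_widths):
            if self.head_weights[i].shape != (w, prev):
                raise ValueError(
                    f"head{i}.weight has shape {self.head_weights[i].shape}, "
                    f"expected {(w, prev)}"
                )
            prev = w
        for name, arr in self.named_arrays():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")


# --------------------------------------------------------------------------
# primitive layers (public, single image or feature map)
# --------------------------------------------------------------------------

def conv2d(image: np.ndarray, kernel: np.ndarray, bias: np.ndarray):
    """Same-size 2-D convolution (cross-correlation) with zero padding.

    ``image`` is (H, W, C), ``kernel`` (O, C, k, k) with odd k, ``bias``
    (O,).  output[y, x, o] = bias[o] + sum over the kxk neighbourhood of
    kernel[o] * image, zero outside the frame.
    """
    image = np.asarray(image, dtype=np.float64)
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.shape[2] % 2 != 1:
        raise ValueError("kernel size must be odd")
    if image.shape[-1] != kernel.shape[1]:
        raise ValueError(
            f"image has {image.shape[-1]} channels but kernel expects "
            f"{kernel.shape[1]}"
        )
    out, _ = _conv_forward(image[None], kernel, np.asarray(bias, float))
    return out[0]


def maxpool2x2(fm: np.ndarray) -> np.ndarray:
    """Disjoint 2x2 max pooling; a trailing odd row/column is dropped."""
    fm = np.asarray(fm, dtype=np.float64)
    if fm.shape[0] < 2 or fm.shape[1] < 2:
        raise ValueError("feature map must be at least 2x2")
    out, _ = _pool_forward(fm[None])
    return out[0]


def flatten(fm: np.ndarray) -> np.ndarray:
    """Row-major flatten: rows, then columns, channels innermost."""
    return np.asarray(fm).reshape(-1)


def dense(x: np.ndarray, W: np.ndarray, b: np.ndarray,
          activation: str = "linear") -> np.ndarray:
    """activation(W x + b) with activation in {relu, linear, sigmoid}."""
    x = np.asarray(x, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if W.shape[1] != x.shape[-1]:
        raise ValueError(
            f"weight expects input of length {W.shape[1]}, got {x.shape[-1]}"
        )
    z = x @ W.T + b
    return _activate(z, activation)


def _activate(z, activation):
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "linear":
        return z
    if activation == "sigmoid":
        return _sigmoid(z)
    raise ValueError(f"unknown activation {activation!r}")


def _sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# --------------------------------------------------------------------------
# batched internals with caches for backpropagation
# --------------------------------------------------------------------------

def _conv_forward(x, kernel, bias):
    """x (N,H,W,C), kernel (O,C,k,k) -> y (N,H,W,O) and the im2col cache."""
    n, h, w, c = x.shape
    o, _, k, _ = kernel.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    # windows: (N, H, W, C, k, k); ravel order (C, kh, kw) matches kernel
    win = sliding_window_view(xp, (k, k), axis=(1, 2))
    cols = win.reshape(n, h, w, c * k * k)
    y = cols @ kernel.reshape(o, -1).T + bias
    return y, cols


def _conv_backward(dy, cols, kernel, x_shape):
    """Gradients of a same-size conv: returns (dx, dkernel, dbias)."""
    n, h, w, c = x_shape
    o, _, k, _ = kernel.shape
    p = k // 2
    dy2 = dy.reshape(-1, o)
    db = dy2.sum(axis=0)
    dk = (dy2.T @ cols.reshape(-1, c * k * k)).reshape(kernel.shape)
    dcols = (dy2 @ kernel.reshape(o, -1)).reshape(n, h, w, c, k, k)
    dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
    for i in range(k):
        for j in range(k):
            dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, :, i, j]
    return dxp[:, p:p + h, p:p + w, :], dk, db


def _pool_forward(x):
    """x (N,H,W,C) -> pooled (N,H//2,W//2,C) and argmax cache."""
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    blocks = x[:, : h2 * 2, : w2 * 2, :].reshape(n, h2, 2, w2, 2, c)
    v = blocks.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dy, idx, x_shape):
    n, h, w, c = x_shape
    h2, w2 = h // 2, w // 2
    dv = np.zeros((n, h2, w2, c, 4))
    np.put_along_axis(dv, idx[..., None], dy[..., None], axis=-1)
    dblocks = dv.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    dx = np.zeros(x_shape)
    dx[:, : h2 * 2, : w2 * 2, :] = dblocks.reshape(n, h2 * 2, w2 * 2, c)
    return dx


class _EncoderCache:
    """Per-stage intermediates of one encoder forward pass."""

    __slots__ = ("x_shapes", "cols", "relu_masks", "pool_idx",
                 "flat", "z_enc", "h")

    def __init__(self):
        self.x_shapes = []
        self.cols = []
        self.relu_masks = []
        self.pool_idx = []


def _encoder_forward(x, params: EncoderParams, config: NetworkConfig):
    """Batched encoder pass; returns (h, cache) with h of shape (N, E)."""
    cache = _EncoderCache()
    cur = np.asarray(x, dtype=np.float64)
    for kern, bias in zip(params.conv_kernels, params.conv_biases):
        cache.x_shapes.append(cur.shape)
        z, cols = _conv_forward(cur, kern, bias)
        cache.cols.append(cols)
        mask = z > 0
        cache.relu_masks.append(mask)
        a = z * mask
        cur, idx = _pool_forward(a)
        cache.pool_idx.append(idx)
    cache.flat = cur.reshape(cur.shape[0], -1)
    cache.z_enc = cache.flat @ params.enc_weight.T + params.enc_bias
    cache.h = np.maximum(cache.z_enc, 0.0)
    return cache.h, cache


def _encoder_backward(dh, cache: _EncoderCache, params: EncoderParams,
                      grads) -> None:
    """Accumulate encoder gradients for one branch into ``grads``.

    ``grads`` carries conv_kernels/conv_biases/enc_weight/enc_bias arrays
    (same shapes as params); shared-weight contributions from the two
    branches sum here because both call this with the same ``grads``.
    """
    dz = dh * (cache.z_enc > 0)
    grads.enc_weight += dz.T @ cache.flat
    grads.enc_bias += dz.sum(axis=0)
    cur = dz @ params.enc_weight
    if params.conv_kernels:
        n = cache.flat.shape[0]
        last_mask = cache.relu_masks[-1]
        pooled_shape = (n,) + cache.pool_idx[-1].shape[1:3] + \
            (last_mask.shape[-1],)
        cur = cur.reshape(pooled_shape)
    for i in reversed(range(len(params.conv_kernels))):
        da = _pool_backward(cur, cache.pool_idx[i],
                            cache.relu_masks[i].shape)
        dzc = da * cache.relu_masks[i]
        cur, dk, db = _conv_backward(
            dzc, cache.cols[i], params.conv_kernels[i], cache.x_shapes[i]
        )
        grads.conv_kernels[i] += dk
        grads.conv_biases[i] += db


def _head_forward(h1, h2, params: EncoderParams, head_mode: str):
    """Similarity head on a batch of encoding pairs -> (g, cache).

    Hidden layers are ReLU; the final unit is a sigmoid so g lies
    strictly inside (0, 1).
    """
    if head_mode == "concat":
        x0 = np.concatenate([h1, h2], axis=1)
    else:
        x0 = np.abs(h1 - h2)
    acts = [x0]
    zs = []
    cur = x0
    n_layers = len(params.head_weights)
    for i, (w, b) in enumerate(zip(params.head_weights, params.head_biases)):
        z = cur @ w.T + b
        zs.append(z)
        cur = _sigmoid(z) if i == n_layers - 1 else np.maximum(z, 0.0)
        acts.append(cur)
    g = acts[-1][:, 0]
    return g, (acts, zs, h1, h2, head_mode)


def _head_backward(dz_out, head_cache, params: EncoderParams, grads):
    """Backprop through the head given d(loss)/d(pre-sigmoid output).

    Returns (dh1, dh2); head weight/bias gradients accumulate in grads.
    """
    acts, zs, h1, h2, head_mode = head_cache
    dz = dz_out  # (N, 1), already through the sigmoid
    for i in reversed(range(len(params.head_weights))):
        grads.head_weights[i] += dz.T @ acts[i]
        grads.head_biases[i] += dz.sum(axis=0)
        dx = dz @ params.head_weights[i]
        if i > 0:
            dz = dx * (zs[i - 1] > 0)
    if head_mode == "concat":
        e = h1.shape[1]
        return dx[:, :e], dx[:, e:]
    sign = np.sign(h1 - h2)
    return dx * sign, -dx * sign


# --------------------------------------------------------------------------
# public encoder / head API
# --------------------------------------------------------------------------

def encode(image: np.ndarray, params: EncoderParams,
           config: NetworkConfig) -> np.ndarray:
    """Encoding h of one image (or a batch, leading axis preserved)."""
    image = np.asarray(image, dtype=np.float64)
    single = image.ndim == 3
    batch = image[None] if single else image
    if batch.shape[1] != config.input_size or \
            batch.shape[2] != config.input_size:
        raise ValueError(
            f"image spatial size {batch.shape[1:3]} does not match "
            f"config input_size {config.input_size}"
        )
    h, _ = _encoder_forward(batch, params, config)
    return h[0] if single else h


def similarity_head(h1: np.ndarray, h2: np.ndarray,
                    params: EncoderParams) -> float:
    """Similarity probability g in (0, 1) for one encoding pair.

    The head mode (concatenation vs absolute difference) is inferred
    from the first head weight's input width.
    """
    h1 = np.asarray(h1, dtype=np.float64)
    h2 = np.asarray(h2, dtype=np.float64)
    single = h1.ndim == 1
    if single:
        h1, h2 = h1[None], h2[None]
    if h1.shape != h2.shape:
        raise ValueError("encodings must have equal shape")
    e = h1.shape[1]
    in_dim = params.head_weights[0].shape[1]
    if in_dim == 2 * e:
        mode = "concat"
    elif in_dim == e:
        mode = "absdiff"
    else:
        raise ValueError(
            f"head expects input of width {in_dim}, incompatible with "
            f"encoding length {e}"
        )
    g, _ = _head_forward(h1, h2, params, mode)
    return float(g[0]) if single else g


@dataclass
class SiameseModel:
    """Bundle of trained parameters and their architecture config."""

    params: EncoderParams
    config: NetworkConfig

    def encode(self, images: np.ndarray) -> np.ndarray:
        return encode(images, self.params, self.config)

    def pair_probability(self, h1, h2):
        """Symmetrised similarity: mean of g(h1,h2) and g(h2,h1)."""
        g_ab = similarity_head(h1, h2, self.params)
        g_ba = similarity_head(h2, h1, self.params)
        return 0.5 * (g_ab + g_ba)
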