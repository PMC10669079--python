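"""Minimal NumPy neural-network core for the CNN-ECA classifier.

Implements exactly the layer set the gesture classifier needs — 2-D
convolution (im2col/tensordot), batch normalisation, ReLU, dropout, dense,
the efficient-channel-attention (ECA) module, and Adam — with explicit
forward/backward passes.  Data layout is channels-last: [batch, H, W, C].

Everything is deterministic given the generators passed in; there is no
global RNG state.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve1d, correlate1d

from .errors import ValidationError


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(np.clip(p[np.arange(n), labels], 1e-12, None)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, p, grad / n


# ---------------------------------------------------------------------------
# ECA primitives
# ---------------------------------------------------------------------------

def eca_kernel_size(C: int, gamma: float = 2.0, b: float = 1.0,
                    tie_break: str = "up") -> int:
    """Adaptive 1-D kernel size: the nearest odd integer to log2(C)/gamma + b/gamma.

    Equidistant cases are resolved by ``tie_break`` ('up' widens the
    receptive field); the result is floored at 1 so K is always an odd
    positive integer.
    """
    if C < 1:
        raise ValidationError("channel count must be >= 1")
    if gamma <= 0:
        raise ValidationError("gamma must be positive")
    x = np.log2(C) / gamma + b / gamma
    lo = 2 * int(np.floor((x - 1) / 2)) + 1  # largest odd <= x
    hi = lo + 2
    d_lo, d_hi = x - lo, hi - x
    if abs(d_lo - d_hi) < 1e-12:
        k = hi if tie_break == "up" else lo
    else:
        k = lo if d_lo < d_hi else hi
    return max(k, 1)


def _eca_core_forward(x4: np.ndarray, w: np.ndarray):
    """x4: [N, H, W, C]; returns (out, cache) with attention over the last axis."""
    reduce_axes = tuple(range(1, x4.ndim - 1))
    m = int(np.prod(x4.shape[1:-1]))
    d = x4.mean(axis=reduce_axes)                    # [N, C]
    logits = correlate1d(d, w, axis=-1, mode="constant", cval=0.0)
    a = sigmoid(logits)                              # [N, C]
    out = x4 * a[:, None, None, :]
    return out, (x4, d, a, w, m)


def _eca_core_backward(dout: np.ndarray, cache):
    x4, d, a, w, m = cache
    da = (dout * x4).sum(axis=(1, 2))                # [N, C]
    dlogit = da * a * (1.0 - a)
    dd = convolve1d(dlogit, w, axis=-1, mode="constant", cval=0.0)
    p = (len(w) - 1) // 2
    dpad = np.pad(d, ((0, 0), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(dpad, len(w), axis=1)  # [N, C, K]
    dw = np.einsum("nck,nc->k", win, dlogit)
    dx = dout * a[:, None, None, :] + dd[:, None, None, :] / m
    return dx, dw


def eca_forward(features: np.ndarray, conv_weights: np.ndarray,
                gamma: float = 2.0, b: float = 1.0) -> np.ndarray:
    """Functional ECA: gate [batch, H, W, C] features by channel attention.

    The channel descriptor is the spatial mean per channel; attention logits
    are its 1-D cross-channel convolution with ``conv_weights`` (same
    padding, zero-padded ends) passed through a sigmoid.  Output shape equals
    input shape.  Any odd-length kernel is accepted.
    """
    features = np.asarray(features, dtype=float)
    w = np.asarray(conv_weights, dtype=float)
    if features.ndim != 4:
        raise ValidationError("features must be [batch, H, W, C]")
    if w.ndim != 1 or w.size % 2 == 0 or w.size < 1:
        raise ValidationError("conv_weights must be a 1-D odd-length kernel")
    out, _ = _eca_core_forward(features, w)
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: trainable ``variables``, non-trainable ``buffers``."""

    def __init__(self):
        self.variables: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, training):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError

    def out_shape(self, in_shape):
        return in_shape

    def n_params(self) -> int:
        return sum(v.size for v in self.variables.values()) + \
            sum(v.size for v in self.buffers.values())


def _same_pad(size: int, k: int, s: int) -> tuple[int, int, int]:
    out = -(-size // s)  # ceil
    total = max((out - 1) * s + k - size, 0)
    return out, total // 2, total - total // 2


class Conv2D(Layer):
    def __init__(self, kh, kw, cin, cout, stride=(1, 1), padding="same", rng=None):
        super().__init__()
        self.kh, self.kw, self.cin, self.cout = kh, kw, cin, cout
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        fan_in, fan_out = kh * kw * cin, kh * kw * cout
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.variables = {
            "W": rng.uniform(-limit, limit, size=(kh, kw, cin, cout)),
            "b": np.zeros(cout),
        }

    def out_shape(self, in_shape):
        h, w, c = in_shape
        if c != self.cin:
            raise ValidationError(f"expected {self.cin} input channels, got {c}")
        sh, sw = self.stride
        if self.padding == "same":
            ho = -(-h // sh)
            wo = -(-w // sw)
        else:
            if h < self.kh or w < self.kw:
                raise ValidationError(
                    f"input {h}x{w} too small for a {self.kh}x{self.kw} kernel "
                    "under valid padding"
                )
            ho = (h - self.kh) // sh + 1
            wo = (w - self.kw) // sw + 1
        return (ho, wo, self.cout)

    def forward(self, x, training):
        sh, sw = self.stride
        n, h, w, c = x.shape
        if self.padding == "same":
            _, pt, pb = _same_pad(h, self.kh, sh)
            _, pl, pr = _same_pad(w, self.kw, sw)
        else:
            pt = pb = pl = pr = 0
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        ho, wo, _ = self.out_shape((h, w, c))
        view = np.lib.stride_tricks.sliding_window_view(xp, (self.kh, self.kw), axis=(1, 2))
        cols = view[:, ::sh, ::sw][:, :ho, :wo]      # [N, Ho, Wo, C, kh, kw]
        out = np.tensordot(cols, self.variables["W"], axes=([4, 5, 3], [0, 1, 2]))
        out += self.variables["b"]
        self._cache = (cols, xp.shape, (pt, pl), x.shape)
        return out

    def backward(self, dout):
        cols, xp_shape, (pt, pl), x_shape = self._cache
        sh, sw = self.stride
        dW = np.tensordot(cols, dout, axes=([0, 1, 2], [0, 1, 2]))  # [C, kh, kw, Cout]
        self.grads["W"] = dW.transpose(1, 2, 0, 3)
        self.grads["b"] = dout.sum(axis=(0, 1, 2))
        dcols = np.tensordot(dout, self.variables["W"], axes=([3], [3]))  # [N,Ho,Wo,kh,kw,C]
        dxp = np.zeros(xp_shape)
        ho, wo = dout.shape[1], dout.shape[2]
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, i:i + sh * ho:sh, j:j + sw * wo:sw, :] += dcols[:, :, :, i, j, :]
        n, h, w, c = x_shape
        return dxp[:, pt:pt + h, pl:pl + w, :]


class BatchNorm(Layer):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.variables = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.buffers = {"running_mean": np.zeros(c), "running_var": np.ones(c)}

    def forward(self, x, training):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.buffers["running_mean"] *= self.momentum
            self.buffers["running_mean"] += (1 - self.momentum) * mean
            self.buffers["running_var"] *= self.momentum
            self.buffers["running_var"] += (1 - self.momentum) * var
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes)
        return self.variables["gamma"] * xhat + self.variables["beta"]

    def backward(self, dout):
        xhat, inv, axes = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.variables["gamma"] * inv
        return g * (dout - dout.mean(axis=axes) - xhat * (dout * xhat).mean(axis=axes))


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    def __init__(self, rate, rng=None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValidationError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, cin, cout, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(6.0 / (cin + cout))
        self.variables = {"W": rng.uniform(-limit, limit, size=(cin, cout)),
                          "b": np.zeros(cout)}

    def out_shape(self, in_shape):
        return (self.variables["W"].shape[1],)

    def forward(self, x, training):
        self._x = x
        return x @ self.variables["W"] + self.variables["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.variables["W"].T


class EcaLayer(Layer):
    """ECA module attending over ``axis`` of the incoming tensor.

    The kernel is initialised to a uniform moving average (1/K), biasing the
    initial attention to track activation magnitude across channels.
    ``last_attention`` holds the [batch, C] attention weights of the most
    recent forward pass, for attention-profile inspection.
    """

    def __init__(self, c, gamma=2.0, b=1.0, tie_break="up", axis=-1):
        super().__init__()
        self.c = c
        self.axis = axis
        self.K = eca_kernel_size(c, gamma, b, tie_break)
        self.variables = {"w": np.full(self.K, 1.0 / self.K)}
        self.last_attention: np.ndarray | None = None

    def _to4(self, x):
        if x.ndim == 2:            # dense features: [N, U] -> [N, 1, 1, U]
            return x[:, None, None, :], None
        if self.axis in (-1, x.ndim - 1):
            return x, None
        xt = np.moveaxis(x, self.axis, -1)
        return xt, self.axis

    def forward(self, x, training):
        x4, moved = self._to4(x)
        self._ndim = x.ndim
        out, cache = _eca_core_forward(x4, self.variables["w"])
        self._cache = cache
        self.last_attention = cache[2]
        if x.ndim == 2:
            return out[:, 0, 0, :]
        return np.moveaxis(out, -1, moved) if moved is not None else out

    def backward(self, dout):
        if self._ndim == 2:
            dout4 = dout[:, None, None, :]
        elif self.axis in (-1, self._ndim - 1):
            dout4 = dout
        else:
            dout4 = np.moveaxis(dout, self.axis, -1)
        dx4, dw = _eca_core_backward(dout4, self._cache)
        self.grads["w"] = dw
        if self._ndim == 2:
            return dx4[:, 0, 0, :]
        if self.axis not in (-1, self._ndim - 1):
            return np.moveaxis(dx4, -1, self.axis)
        return dx4


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def state(self):
        """Deep copies of every variable and buffer (checkpointing)."""
        return [({k: v.copy() for k, v in l.variables.items()},
                 {k: v.copy() for k, v in l.buffers.items()}) for l in self.layers]

    def load_state(self, state):
        for layer, (variables, buffers) in zip(self.layers, state):
            for k, v in variables.items():
                layer.variables[k] = v.copy()
            for k, v in buffers.items():
                layer.buffers[k] = v.copy()

    def trainables(self):
        for li, layer in enumerate(self.layers):
            for k in layer.variables:
                yield li, k


class Adam:
    def __init__(self, model: Sequential, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {key: np.zeros_like(model.layers[li].variables[k])
                  for key in model.trainables() for li, k in [key]}
        self.v = {key: np.zeros_like(model.layers[li].variables[k])
                  for key in model.trainables() for li, k in [key]}

    def step(self):
        self.t += 1
        for li, k in self.model.trainables():
            g = self.model.layers[li].grads[k]
            key = (li, k)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            self.model.layers[li].variables[k] -= \
                self.lr * mhat / (np.sqrt(vhat) + self.eps)
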