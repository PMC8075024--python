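"""Layer primitives with forward/backward passes.

Tensor layout is ``(batch, length, channels)`` for sequence layers and
``(batch, features)`` after :class:`Flatten`.  Convolutions use "same"
padding so a stride-``s`` layer maps length ``L`` to ``ceil(L/s)``.
Parameters live in ``self.params`` (name -> array) with matching gradients
in ``self.grads`` after a backward pass.
"""

from __future__ import annotations

import numpy as np


class Layer:
    kind: str = "layer"
    trainable: bool = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))


def _same_pad(L: int, k: int, stride: int) -> tuple[int, int, int]:
    """(out_len, pad_left, pad_right) for "same" padding."""
    out_len = -(-L // stride)  # ceil
    pad_total = max((out_len - 1) * stride + k - L, 0)
    pad_left = pad_total // 2
    return out_len, pad_left, pad_total - pad_left


def _tap(xp: np.ndarray, kk: int, stride: int, out_len: int) -> np.ndarray:
    """The kk-th kernel-tap slice of the padded input: (N, out_len, C)."""
    return xp[:, kk : kk + stride * out_len : stride]


class Conv1D(Layer):
    """Standard 1-D convolution, weights (k, c_in, c_out), optional bias."""

    kind = "conv1d"

    def __init__(self, k: int, c_in: int, c_out: int, stride: int = 1,
                 bias: bool = False, rng: np.random.Generator | None = None,
                 activation: "Layer | None" = None):
        super().__init__()
        self.k, self.c_in, self.c_out, self.stride = k, c_in, c_out, stride
        self.activation = activation  # fused: not a separate census layer
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (k * c_in))
        self.params["w"] = rng.normal(0.0, scale, size=(k, c_in, c_out))
        if bias:
            self.params["b"] = np.zeros(c_out)

    def forward(self, x, train=False):
        N, L, C = x.shape
        out_len, pl, pr = _same_pad(L, self.k, self.stride)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        self._cache = (xp, pl, L, out_len)
        w = self.params["w"]
        y = _tap(xp, 0, self.stride, out_len) @ w[0]
        for kk in range(1, self.k):
            y += _tap(xp, kk, self.stride, out_len) @ w[kk]
        if "b" in self.params:
            y += self.params["b"]
        return self.activation.forward(y, train) if self.activation else y

    def backward(self, dy):
        if self.activation:
            dy = self.activation.backward(dy)
        xp, pl, L, out_len = self._cache
        w = self.params["w"]
        dyf = dy.reshape(-1, dy.shape[-1])
        dw = np.empty_like(w)
        dxp = np.zeros_like(xp)
        for kk in range(self.k):
            xs = _tap(xp, kk, self.stride, out_len)
            dw[kk] = xs.reshape(-1, xs.shape[-1]).T @ dyf
            dxp[:, kk : kk + self.stride * out_len : self.stride] += dy @ w[kk].T
        self.grads["w"] = dw
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 1))
        return dxp[:, pl : pl + L]


class SepConv1D(Layer):
    """Depthwise separable 1-D convolution (depth multiplier 1).

    A per-channel spatial convolution (weights ``(k, c_in)``, stride applied
    here) followed by a 1-tap pointwise convolution (weights
    ``(c_in, c_out)``): ``k*c_in + c_in*c_out`` weights in place of the
    standard layer's ``k*c_in*c_out``.
    """

    kind = "sepconv1d"

    def __init__(self, k: int, c_in: int, c_out: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.k, self.c_in, self.c_out, self.stride = k, c_in, c_out, stride
        rng = rng or np.random.default_rng()
        self.params["dw"] = rng.normal(0.0, np.sqrt(2.0 / k), size=(k, c_in))
        self.params["pw"] = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out))

    def forward(self, x, train=False):
        N, L, C = x.shape
        out_len, pl, pr = _same_pad(L, self.k, self.stride)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        dw = self.params["dw"]
        mid = _tap(xp, 0, self.stride, out_len) * dw[0]
        for kk in range(1, self.k):
            mid += _tap(xp, kk, self.stride, out_len) * dw[kk]
        self._cache = (xp, mid, pl, L, out_len)
        return mid @ self.params["pw"]

    def backward(self, dy):
        xp, mid, pl, L, out_len = self._cache
        dw, pw = self.params["dw"], self.params["pw"]
        self.grads["pw"] = mid.reshape(-1, mid.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        dmid = dy @ pw.T
        d_dw = np.empty_like(dw)
        dxp = np.zeros_like(xp)
        for kk in range(self.k):
            xs = _tap(xp, kk, self.stride, out_len)
            d_dw[kk] = (xs * dmid).sum(axis=(0, 1))
            dxp[:, kk : kk + self.stride * out_len : self.stride] += dmid * dw[kk]
        self.grads["dw"] = d_dw
        return dxp[:, pl : pl + L]


class BatchNorm(Layer):
    """Batch normalization over (batch, length) per channel."""

    kind = "batchnorm"

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            xhat = x - mu
            flat = xhat.reshape(-1, x.shape[-1])
            var = np.einsum("nc,nc->c", flat, flat) / flat.shape[0]
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mu).astype(x.dtype)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(x.dtype)
            inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
            xhat *= inv
            self._cache = (xhat, inv, axes)
            return self.params["gamma"] * xhat + self.params["beta"]
        # inference: single fused affine pass
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = (self.params["gamma"] * inv).astype(x.dtype)
        shift = (self.params["beta"] - self.running_mean * scale).astype(x.dtype)
        return x * scale + shift

    def backward(self, dy):
        xhat, inv, axes = self._cache
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        # assumes forward ran in train mode on the same batch
        g = self.params["gamma"] * inv
        return g * (dy - dy.mean(axis=axes) - xhat * (dy * xhat).mean(axis=axes))


class ELU(Layer):
    """Exponential linear unit: x for x > 0, alpha*(exp(x)-1) otherwise."""

    kind = "activation"
    trainable = False

    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=False):
        # max(x,0) + alpha*expm1(min(x,0)) == elu(x), branch-free
        neg = np.minimum(x, 0)
        np.expm1(neg, out=neg)
        if self.alpha != 1.0:
            neg *= self.alpha
        y = np.maximum(x, 0)
        y += neg
        self._cache = (x > 0, y)
        return y

    def backward(self, dy):
        pos, y = self._cache
        # derivative: 1 where x>0, else alpha*exp(x) = y + alpha
        d = y + self.alpha
        np.copyto(d, 1.0, where=pos, casting="unsafe")
        return dy * d


class MaxPool1D(Layer):
    kind = "maxpool"
    trainable = False

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=False):
        N, L, C = x.shape
        out_len = L // self.pool
        xt = x[:, : out_len * self.pool].reshape(N, out_len, self.pool, C)
        idx = xt.argmax(axis=2)
        self._cache = (idx, x.shape, out_len)
        return np.take_along_axis(xt, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        idx, x_shape, out_len = self._cache
        N, L, C = x_shape
        dxt = np.zeros((N, out_len, self.pool, C), dtype=dy.dtype)
        np.put_along_axis(dxt, idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(x_shape, dtype=dy.dtype)
        dx[:, : out_len * self.pool] = dxt.reshape(N, out_len * self.pool, C)
        return dx


class Flatten(Layer):
    kind = "flatten"
    trainable = False

    def forward(self, x, train=False):
        self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._cache)


class Dense(Layer):
    kind = "dense"

    def __init__(self, n_in: int, n_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None,
                 activation: "Layer | None" = None):
        super().__init__()
        self.activation = activation  # fused: not a separate census layer
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.params["w"] = rng.uniform(-limit, limit, size=(n_in, n_out))
        if bias:
            self.params["b"] = np.zeros(n_out)

    def forward(self, x, train=False):
        self._cache = x
        y = x @ self.params["w"]
        if "b" in self.params:
            y += self.params["b"]
        return self.activation.forward(y, train) if self.activation else y

    def backward(self, dy):
        if self.activation:
            dy = self.activation.backward(dy)
        x = self._cache
        self.grads["w"] = x.T @ dy
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["w"].T


class Dropout(Layer):
    kind = "dropout"
    trainable = False

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._cache = None
            return x
        mask = (self.rng.random(x.shape) >= self.p).astype(x.dtype)
        mask /= np.asarray(1.0 - self.p, dtype=x.dtype)
        self._cache = mask
        return x * mask

    def backward(self, dy):
        return dy if self._cache is None else dy * self._cache


class Softmax(Layer):
    """Row-wise softmax producing class probabilities."""

    kind = "softmax"
    trainable = False

    def forward(self, x, train=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        self._cache = p
        return p

    def backward(self, dp):
        p = self._cache
        return p * (dp - (dp * p).sum(axis=-1, keepdims=True))
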