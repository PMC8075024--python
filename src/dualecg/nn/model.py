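"""Two-branch sequential model container with SGD training support."""

from __future__ import annotations

import copy

import numpy as np

from .layers import Layer


class DualBranchModel:
    """Two input branches merged by concatenation, followed by a trunk.

    ``concat_axis=1`` joins the branch outputs along the time axis (both
    branches must produce the same channel count); the final trunk layer is
    expected to be a :class:`Softmax` producing class probabilities.
    """

    def __init__(self, branch1: list[Layer], branch2: list[Layer],
                 trunk: list[Layer], concat_axis: int = 1,
                 dtype=np.float32):
        self.branch1, self.branch2, self.trunk = branch1, branch2, trunk
        self.concat_axis = concat_axis
        self.dtype = np.dtype(dtype)
        for l in self.layers:
            for name in l.params:
                l.params[name] = l.params[name].astype(self.dtype)
            if l.kind == "batchnorm":
                l.running_mean = l.running_mean.astype(self.dtype)
                l.running_var = l.running_var.astype(self.dtype)

    # -- structure ---------------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        return self.branch1 + self.branch2 + self.trunk

    def param_count(self) -> int:
        return sum(l.param_count() for l in self.layers)

    def conv_param_counts(self) -> list[tuple[str, int, int, int, int]]:
        """Introspected (kind, k, c_in, c_out, n_params) per conv-type layer."""
        out = []
        for l in self.layers:
            if l.kind in ("conv1d", "sepconv1d"):
                out.append((l.kind, l.k, l.c_in, l.c_out, l.param_count()))
        return out

    def census(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for l in self.layers:
            counts[l.kind] = counts.get(l.kind, 0) + 1
        counts["conv_total"] = counts.get("conv1d", 0) + counts.get("sepconv1d", 0)
        return counts

    # -- forward / backward ------------------------------------------------
    def forward(self, x1: np.ndarray, x2: np.ndarray, train: bool = False) -> np.ndarray:
        if x1.ndim == 2:  # (N, L) -> single-channel (N, L, 1)
            x1 = x1[..., None]
        if x2.ndim == 2:
            x2 = x2[..., None]
        x1 = np.ascontiguousarray(x1, dtype=self.dtype)
        x2 = np.ascontiguousarray(x2, dtype=self.dtype)
        for l in self.branch1:
            x1 = l.forward(x1, train)
        for l in self.branch2:
            x2 = l.forward(x2, train)
        self._split = x1.shape[self.concat_axis]
        z = np.concatenate([x1, x2], axis=self.concat_axis)
        for l in self.trunk:
            z = l.forward(z, train)
        return z

    def backward(self, dy: np.ndarray) -> None:
        for l in reversed(self.trunk):
            dy = l.backward(dy)
        d1, d2 = np.split(dy, [self._split], axis=self.concat_axis)
        for l in reversed(self.branch1):
            d1 = l.backward(d1)
        for l in reversed(self.branch2):
            d2 = l.backward(d2)

    def sgd_step(self, lr: float) -> None:
        for l in self.layers:
            for name, p in l.params.items():
                p -= lr * l.grads[name]

    # -- inference ---------------------------------------------------------
    def predict_proba(self, x1: np.ndarray, x2: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, x1.shape[0], batch_size):
            out.append(self.forward(x1[i : i + batch_size], x2[i : i + batch_size],
                                    train=False))
        return np.concatenate(out)

    def predict(self, x1: np.ndarray, x2: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(x1, x2, batch_size).argmax(axis=1)

    # -- weight snapshots (early stopping) ---------------------------------
    def get_weights(self):
        return [copy.deepcopy(l.params) for l in self.layers] + [
            copy.deepcopy((l.running_mean, l.running_var))
            for l in self.layers if l.kind == "batchnorm"
        ]

    def set_weights(self, snapshot) -> None:
        n_layers = len(self.layers)
        params, bn_stats = snapshot[:n_layers], snapshot[n_layers:]
        for l, p in zip(self.layers, params):
            for name in l.params:
                l.params[name][...] = p[name]
        bn_layers = [l for l in self.layers if l.kind == "batchnorm"]
        for l, (rm, rv) in zip(bn_layers, bn_stats):
            l.running_mean[...] = rm
            l.running_var[...] = rv
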