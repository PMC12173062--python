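"""Minimal numpy neural-network layers with manual backpropagation.

Provides exactly what the vocalization recognizer needs: 2-D convolutions
with "same" padding and per-axis strides (ceil-mode output sizes), batch
normalization, ReLU, a frequency mean-pool, and an Adam optimizer.  All
computation is float32; forward passes in eval mode are pure functions of
(parameters, input).  Gradients are verified against finite differences in
the test suite.

Tensor layout is (N, C, T, F): batch, channels, time frames, mel bands.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["Param", "Conv2d", "BatchNorm2d", "ReLU", "FreqMeanPool", "Sequential", "Adam"]


class Param:
    """A trainable tensor with its gradient accumulator."""

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    """Ceil-mode 'same' padding: output length, pad_before, pad_after."""
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    return out, total // 2, total - total // 2


class Conv2d:
    """2-D convolution (cross-correlation), 'same' zero padding, bias."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int] = (3, 3),
        stride: tuple[int, int] = (1, 1),
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        kt, kf = kernel
        fan_in = in_channels * kt * kf
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.weight = Param(rng.standard_normal((out_channels, in_channels, kt, kf)) * scale)
        self.bias = Param(np.zeros(out_channels))
        self.stride = stride
        self.kernel = kernel
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        N, C, T, F = x.shape
        kt, kf = self.kernel
        st, sf = self.stride
        oT, pt0, pt1 = _same_pad(T, kt, st)
        oF, pf0, pf1 = _same_pad(F, kf, sf)
        xp = np.pad(x, ((0, 0), (0, 0), (pt0, pt1), (pf0, pf1)))
        # gather kernel taps as (N, oT, oF, C*kt*kf)
        cols = np.empty((N, oT, oF, C, kt, kf), dtype=np.float32)
        for i in range(kt):
            for j in range(kf):
                cols[:, :, :, :, i, j] = xp[
                    :, :, i : i + st * oT : st, j : j + sf * oF : sf
                ].transpose(0, 2, 3, 1)
        cols2 = cols.reshape(N * oT * oF, C * kt * kf)
        Wm = self.weight.value.reshape(self.weight.value.shape[0], -1)
        y = cols2 @ Wm.T + self.bias.value
        y = y.reshape(N, oT, oF, -1).transpose(0, 3, 1, 2)
        if train:
            self._cache = (x.shape, xp.shape, cols2, (pt0, pf0), (oT, oF))
        return np.ascontiguousarray(y)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (xshape, xpshape, cols2, (pt0, pf0), (oT, oF)) = self._cache
        N, C, T, F = xshape
        kt, kf = self.kernel
        st, sf = self.stride
        dout2 = dout.transpose(0, 2, 3, 1).reshape(-1, dout.shape[1])
        Wm = self.weight.value.reshape(self.weight.value.shape[0], -1)
        self.weight.grad += (dout2.T @ cols2).reshape(self.weight.value.shape)
        self.bias.grad += dout2.sum(axis=0)
        dcols = (dout2 @ Wm).reshape(N, oT, oF, C, kt, kf)
        dxp = np.zeros(xpshape, dtype=np.float32)
        for i in range(kt):
            for j in range(kf):
                dxp[:, :, i : i + st * oT : st, j : j + sf * oF : sf] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        self._cache = None
        return dxp[:, :, pt0 : pt0 + T, pf0 : pf0 + F]


class BatchNorm2d:
    """Per-channel batch normalization over (N, T, F) with running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        g = self.gamma.value[None, :, None, None]
        b = self.beta.value[None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            xhat = (x - mean[None, :, None, None]) / np.sqrt(var[None, :, None, None] + self.eps)
            self._cache = (xhat, var)
            return (g * xhat + b).astype(np.float32)
        xhat = (x - self.running_mean[None, :, None, None]) / np.sqrt(
            self.running_var[None, :, None, None] + self.eps
        )
        return (g * xhat + b).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, var = self._cache
        self._cache = None
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dout * g
        inv_std = 1.0 / np.sqrt(var[None, :, None, None] + self.eps)
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv_std
        return dx.astype(np.float32)


class ReLU:
    params: list[Param] = []

    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class FreqMeanPool:
    """Collapse the frequency axis to width 1 by averaging."""

    params: list[Param] = []

    def __init__(self) -> None:
        self._width = 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._width = x.shape[3]
        return x.mean(axis=3, keepdims=True)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout / self._width, self._width, axis=3)


class Sequential:
    def __init__(self, layers: Sequence) -> None:
        self.layers = list(layers)

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class Adam:
    def __init__(self, params: Sequence[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self, trainable: Sequence[Param] | None = None) -> None:
        """Apply one update; if ``trainable`` is given, only those params move."""
        allow = None if trainable is None else {id(p) for p in trainable}
        self.t += 1
        for i, p in enumerate(self.params):
            if allow is not None and id(p) not in allow:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
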