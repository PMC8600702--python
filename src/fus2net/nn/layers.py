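"""Minimal channels-last neural-network layers with hand-derived backprop.

All tensors are float32 ``(N, H, W, C)`` (or ``(N, D)`` after flattening).
Convolution is computed by im2col + GEMM; its gradient scatters back through
the same window geometry. Padding follows the two standard conventions:
``valid`` (windows fully inside, output floor((n-f)/s)+1) and ``same``
(symmetric zero-pad so that stride-1 output size equals input size).
Every layer's backward pass is verified against central finite differences
in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _pair(v) -> tuple[int, int]:
    if isinstance(v, int):
        return (v, v)
    return (int(v[0]), int(v[1]))


def truncated_normal(rng: np.random.Generator, shape, std: float) -> np.ndarray:
    """Normal(0, std) resampled until within two standard deviations."""
    out = rng.standard_normal(shape)
    bad = np.abs(out) > 2.0
    while bad.any():
        out[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(out) > 2.0
    return (out * std).astype(DTYPE)


def _same_pad(n: int, f: int, s: int) -> tuple[int, int]:
    out = -(-n // s)  # ceil
    total = max((out - 1) * s + f - n, 0)
    return total // 2, total - total // 2


class Layer:
    """Base layer: stateless unless it owns parameters."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, inputs: list[np.ndarray], training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        raise NotImplementedError

    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def l2_penalty(self) -> float:
        return 0.0


class Conv2D(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel,
        stride=1,
        padding: str = "valid",
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.fh, self.fw = _pair(kernel)
        self.sh, self.sw = _pair(stride)
        if padding not in ("valid", "same"):
            raise ValueError(f"padding must be 'valid' or 'same', got {padding!r}")
        self.padding = padding
        self.cin, self.cout = in_channels, out_channels
        rng = rng or np.random.default_rng()
        fan_in = self.fh * self.fw * in_channels
        # weight layout (cin, fh, fw, cout) flattened, matching im2col order
        self.params["W"] = truncated_normal(
            rng, (in_channels * self.fh * self.fw, out_channels), np.sqrt(2.0 / fan_in)
        )
        self.params["b"] = np.zeros(out_channels, dtype=DTYPE)

    def out_spatial(self, h: int, w: int) -> tuple[int, int]:
        if self.padding == "valid":
            return (h - self.fh) // self.sh + 1, (w - self.fw) // self.sw + 1
        return -(-h // self.sh), -(-w // self.sw)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        if self.padding == "same":
            ph = _same_pad(x.shape[1], self.fh, self.sh)
            pw = _same_pad(x.shape[2], self.fw, self.sw)
            x = np.pad(x, ((0, 0), ph, pw, (0, 0)))
        self._padded_shape = x.shape
        win = sliding_window_view(x, (self.fh, self.fw), axis=(1, 2))
        win = win[:, :: self.sh, :: self.sw]  # (N, Ho, Wo, C, fh, fw)
        self._out_hw = win.shape[1:3]
        return np.ascontiguousarray(win)

    def forward(self, inputs, training):
        (x,) = inputs
        self._in_shape = x.shape
        cols = self._im2col(x)
        n, ho, wo = cols.shape[0], cols.shape[1], cols.shape[2]
        flat = cols.reshape(n * ho * wo, -1)
        self._cols = flat
        out = flat @ self.params["W"] + self.params["b"]
        return out.reshape(n, ho, wo, self.cout)

    def backward(self, dout):
        n, ho, wo, _ = dout.shape
        dflat = dout.reshape(n * ho * wo, self.cout)
        self.grads["W"] = self._cols.T @ dflat
        self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"].T).reshape(
            n, ho, wo, self.cin, self.fh, self.fw
        )
        dx_pad = np.zeros(self._padded_shape, dtype=DTYPE)
        for i in range(self.fh):
            for j in range(self.fw):
                dx_pad[
                    :, i : i + ho * self.sh : self.sh, j : j + wo * self.sw : self.sw
                ] += dcols[:, :, :, :, i, j]
        if self.padding == "same":
            ph = _same_pad(self._in_shape[1], self.fh, self.sh)
            pw = _same_pad(self._in_shape[2], self.fw, self.sw)
            dx_pad = dx_pad[
                :,
                ph[0] : dx_pad.shape[1] - ph[1],
                pw[0] : dx_pad.shape[2] - pw[1],
            ]
        return [dx_pad]


class _Pool(Layer):
    """Shared window plumbing for max / average pooling (valid padding)."""

    def __init__(self, pool, stride) -> None:
        super().__init__()
        self.fh, self.fw = _pair(pool)
        self.sh, self.sw = _pair(stride)

    def _windows(self, x):
        win = sliding_window_view(x, (self.fh, self.fw), axis=(1, 2))
        win = win[:, :: self.sh, :: self.sw]  # (N, Ho, Wo, C, fh, fw)
        return win.reshape(win.shape[:4] + (self.fh * self.fw,))

    def _scatter(self, weights, dout):
        """Route dout back through each window position weighted by `weights`."""
        n, ho, wo, c, _ = weights.shape
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        for k in range(self.fh * self.fw):
            i, j = divmod(k, self.fw)
            dx[
                :, i : i + ho * self.sh : self.sh, j : j + wo * self.sw : self.sw
            ] += dout * weights[..., k]
        return [dx]


class MaxPool2D(_Pool):
    def forward(self, inputs, training):
        (x,) = inputs
        self._in_shape = x.shape
        win = self._windows(x)
        self._arg = np.argmax(win, axis=-1)
        return np.max(win, axis=-1)

    def backward(self, dout):
        k = self.fh * self.fw
        onehot = np.eye(k, dtype=DTYPE)[self._arg]
        return self._scatter(onehot, dout)


class AvgPool2D(_Pool):
    def forward(self, inputs, training):
        (x,) = inputs
        self._in_shape = x.shape
        return self._windows(x).mean(axis=-1)

    def backward(self, dout):
        k = self.fh * self.fw
        shape = dout.shape + (k,)
        weights = np.full(shape, 1.0 / k, dtype=DTYPE)
        return self._scatter(weights, dout)


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W).

    Trainable scale/shift plus running statistics for inference; the
    parameter count therefore reads 4 per channel (gamma, beta, moving mean,
    moving variance), of which two are trainable.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-3):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def param_count(self) -> int:
        return int(self.params["gamma"].size * 4)

    def forward(self, inputs, training):
        (x,) = inputs
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        self._ivar = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._ivar
        self._m = int(np.prod([x.shape[a] for a in axes])) or 1
        self._training = training
        return (self.params["gamma"] * self._xhat + self.params["beta"]).astype(DTYPE)

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        self.grads["gamma"] = (dout * self._xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"]
        if not self._training:
            return [dout * g * self._ivar]
        m = self._m
        dxhat = dout * g
        dx = (
            self._ivar
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes)
                - self._xhat * (dxhat * self._xhat).sum(axis=axes)
            )
        )
        return [dx.astype(DTYPE)]


class ReLU(Layer):
    def forward(self, inputs, training):
        (x,) = inputs
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return [dout * self._mask]


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        l2: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.l2 = l2
        self.params["W"] = truncated_normal(
            rng, (in_features, out_features), np.sqrt(2.0 / in_features)
        )
        self.params["b"] = np.zeros(out_features, dtype=DTYPE)

    def forward(self, inputs, training):
        (x,) = inputs
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout + 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = dout.sum(axis=0)
        return [dout @ self.params["W"].T]

    def l2_penalty(self) -> float:
        # Keras convention: l2 * sum(w^2), no 1/2 factor
        return float(self.l2 * np.sum(self.params["W"].astype(np.float64) ** 2))


class Dropout(Layer):
    def __init__(self, rate: float, seed: int = 0):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.reseed(seed)

    def reseed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def forward(self, inputs, training):
        (x,) = inputs
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return [dout]
        return [dout * self._mask]


class Flatten(Layer):
    def forward(self, inputs, training):
        (x,) = inputs
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return [dout.reshape(self._shape)]


class Concat(Layer):
    """Channel-axis concatenation; requires equal spatial dimensions."""

    def forward(self, inputs, training):
        spatial = {x.shape[1:3] for x in inputs}
        if len(spatial) != 1:
            raise ValueError(f"concat inputs differ spatially: {sorted(spatial)}")
        self._splits = np.cumsum([x.shape[-1] for x in inputs])[:-1]
        return np.concatenate(inputs, axis=-1)

    def backward(self, dout):
        return list(np.split(dout, self._splits, axis=-1))


class Add(Layer):
    """Elementwise sum of identically shaped tensors."""

    def forward(self, inputs, training):
        shapes = {x.shape for x in inputs}
        if len(shapes) != 1:
            raise ValueError(f"add inputs differ in shape: {sorted(shapes)}")
        self._n = len(inputs)
        out = inputs[0].copy()
        for x in inputs[1:]:
            out += x
        return out

    def backward(self, dout):
        return [dout] * self._n


class Scale(Layer):
    """Multiplication by a fixed constant (the residual-branch scale)."""

    def __init__(self, factor: float):
        super().__init__()
        self.factor = DTYPE(factor)

    def forward(self, inputs, training):
        (x,) = inputs
        return x * self.factor

    def backward(self, dout):
        return [dout * self.factor]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(DTYPE)
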