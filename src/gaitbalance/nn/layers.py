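"""Layers with explicit forward/backward passes.

Data layout is ``(N, C, T)``: batch, channels, time.  Convolutions use
"same" padding (odd kernels), so the time axis length is preserved
throughout the network.  Parameters are float32 for speed; every layer
exposes ``params`` and matching ``grads`` lists for the optimizers.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def conv1d_raw(x: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Bias-free same-padded 1D convolution (cross-correlation).

    ``x``: (N, C_in, T); ``weight``: (C_out, C_in, K) with K odd.
    Returns (N, C_out, T).
    """
    return np.matmul(weight.reshape(weight.shape[0], -1), _im2col(x, weight.shape[2]))


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Unfold (N, C, T) into (N, C*K, T) columns with same padding."""
    n, c, t = x.shape
    pad = k // 2
    if pad:
        xp = np.zeros((n, c, t + 2 * pad), dtype=x.dtype)
        xp[:, :, pad:pad + t] = x
    else:
        xp = x
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    return np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(n, c * k, t)


def conv1d_input_grad(g: np.ndarray, weight: np.ndarray, t_in: int) -> np.ndarray:
    """Gradient of :func:`conv1d_raw` w.r.t. its input (the transpose op).

    ``g``: (N, C_out, T); returns (N, C_in, t_in).
    """
    c_out, c_in, k = weight.shape
    pad = k // 2
    n = g.shape[0]
    w2 = weight.reshape(c_out, c_in * k)
    gcols = np.matmul(w2.T, g).reshape(n, c_in, k, -1)
    gx = np.zeros((n, c_in, t_in + 2 * pad), dtype=g.dtype)
    for j in range(k):
        gx[:, :, j:j + t_in] += gcols[:, :, j, :]
    return gx[:, :, pad:pad + t_in] if pad else gx


class Layer:
    """Base class: parameterless identity."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True) -> None:
        super().__init__()
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError(f"kernel size must be odd and >= 1, got {kernel}")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        std = np.sqrt(2.0 / (c_in * kernel))
        self.weight = rng.normal(0.0, std, (c_out, c_in, kernel)).astype(DTYPE)
        self.bias = np.zeros(c_out, dtype=DTYPE) if bias else None
        self.gw = np.zeros_like(self.weight)
        self.params = [self.weight]
        self.grads = [self.gw]
        if bias:
            self.gb = np.zeros_like(self.bias)
            self.params.append(self.bias)
            self.grads.append(self.gb)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._t_in = x.shape[2]
        self._cols = _im2col(x, self.kernel)
        y = np.matmul(self.weight.reshape(self.c_out, -1), self._cols)
        if self.bias is not None:
            y += self.bias[None, :, None]
        return y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gw2 = np.matmul(gout, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.gw[...] = gw2.reshape(self.weight.shape)
        if self.bias is not None:
            self.gb[...] = gout.sum(axis=(0, 2))
        return conv1d_input_grad(gout, self.weight, self._t_in)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over the batch and time axes."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(c, dtype=DTYPE)
        self.beta = np.zeros(c, dtype=DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.params = [self.gamma, self.beta]
        self.grads = [self.ggamma, self.gbeta]
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = np.square(x).mean(axis=(0, 2)) - np.square(mean)
            np.maximum(var, 0.0, out=var)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * invstd[None, :, None]
        self._invstd = invstd
        self._m = x.shape[0] * x.shape[2]
        self._training = training
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, invstd, m = self._xhat, self._invstd, self._m
        self.ggamma[...] = (gout * xhat).sum(axis=(0, 2))
        self.gbeta[...] = gout.sum(axis=(0, 2))
        gxhat = gout * self.gamma[None, :, None]
        if not self._training:
            return gxhat * invstd[None, :, None]
        return (invstd[None, :, None] / m) * (
            m * gxhat
            - gxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=(0, 2), keepdims=True)
        )

    def effective_affine(self) -> tuple[np.ndarray, np.ndarray]:
        """Inference-mode scale and shift: ``y = scale * x + shift``."""
        scale = self.gamma / np.sqrt(self.running_var + self.eps)
        shift = self.beta - self.running_mean * scale
        return scale, shift


class Activation(Layer):
    """ReLU, or identity when ``kind='identity'`` (linearity test hook)."""

    def __init__(self, kind: str = "relu") -> None:
        super().__init__()
        if kind not in ("relu", "identity"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if self.kind == "identity":
            self._mask = None
            return x
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gout
        return gout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference.  ``rng`` is set by the trainer."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout.rng must be set before training")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return gout
        return gout * self._mask


class GlobalAvgPool(Layer):
    """Mean over the time axis: (N, C, T) -> (N, C)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.repeat(gout[:, :, None], self._t, axis=2) / self._t


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True) -> None:
        super().__init__()
        std = np.sqrt(2.0 / d_in)
        self.weight = rng.normal(0.0, std, (d_out, d_in)).astype(DTYPE)
        self.bias = np.zeros(d_out, dtype=DTYPE) if bias else None
        self.gw = np.zeros_like(self.weight)
        self.params = [self.weight]
        self.grads = [self.gw]
        if bias:
            self.gb = np.zeros_like(self.bias)
            self.params.append(self.bias)
            self.grads.append(self.gb)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        y = x @ self.weight.T
        if self.bias is not None:
            y += self.bias
        return y

    def backward(self, gout: np.ndarray) -> np.ndarray:
        self.gw[...] = gout.T @ self._x
        if self.bias is not None:
            self.gb[...] = gout.sum(axis=0)
        return gout @ self.weight


class ResidualBlock(Layer):
    """conv(k1)-BN-ReLU -> conv(k2)-BN-ReLU -> conv(k3)-BN-ReLU, plus skip.

    The block input is added to the branch output after the third ReLU; a
    bias-free 1-wide convolution projects the skip path when the channel
    counts differ.
    """

    def __init__(self, c_in: int, c_out: int, kernels: tuple[int, int, int],
                 rng: np.random.Generator, activation: str = "relu") -> None:
        super().__init__()
        k1, k2, k3 = kernels
        self.conv1 = Conv1d(c_in, c_out, k1, rng)
        self.bn1 = BatchNorm1d(c_out)
        self.act1 = Activation(activation)
        self.conv2 = Conv1d(c_out, c_out, k2, rng)
        self.bn2 = BatchNorm1d(c_out)
        self.act2 = Activation(activation)
        self.conv3 = Conv1d(c_out, c_out, k3, rng)
        self.bn3 = BatchNorm1d(c_out)
        self.act3 = Activation(activation)
        self.proj = Conv1d(c_in, c_out, 1, rng, bias=False) if c_in != c_out else None
        self._branch = [self.conv1, self.bn1, self.act1,
                        self.conv2, self.bn2, self.act2,
                        self.conv3, self.bn3, self.act3]
        for sub in self.sublayers():
            self.params.extend(sub.params)
            self.grads.extend(sub.grads)

    def sublayers(self) -> list[Layer]:
        subs = list(self._branch)
        if self.proj is not None:
            subs.append(self.proj)
        return subs

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x
        for layer in self._branch:
            h = layer.forward(h, training)
        skip = self.proj.forward(x, training) if self.proj is not None else x
        self._branch_out = h
        self._skip_out = skip
        return h + skip

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = gout
        for layer in reversed(self._branch):
            g = layer.backward(g)
        if self.proj is not None:
            g = g + self.proj.backward(gout)
        else:
            g = g + gout
        return g
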