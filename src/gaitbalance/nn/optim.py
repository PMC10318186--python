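"""First-order optimizers operating in place on a layer's parameter arrays."""

from __future__ import annotations

import numpy as np


class Optimizer:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float) -> None:
        if len(params) != len(grads):
            raise ValueError("params and grads must pair up")
        self.params = params
        self.grads = grads
        self.lr = lr

    def step(self) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    """Plain stochastic gradient descent."""

    def step(self) -> None:
        for p, g in zip(self.params, self.grads):
            p -= self.lr * g


class RMSprop(Optimizer):
    def __init__(self, params, grads, lr, alpha: float = 0.99,
                 eps: float = 1e-8) -> None:
        super().__init__(params, grads, lr)
        self.alpha = alpha
        self.eps = eps
        self.sq = [np.zeros_like(p) for p in params]

    def step(self) -> None:
        for p, g, s in zip(self.params, self.grads, self.sq):
            s *= self.alpha
            s += (1.0 - self.alpha) * g * g
            p -= self.lr * g / (np.sqrt(s) + self.eps)


class Adam(Optimizer):
    def __init__(self, params, grads, lr, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        super().__init__(params, grads, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


_OPTIMIZERS = {"sgd": SGD, "rmsprop": RMSprop, "adam": Adam}


def make_optimizer(name: str, params, grads, lr: float) -> Optimizer:
    try:
        cls = _OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}"
        ) from None
    return cls(params, grads, lr)
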