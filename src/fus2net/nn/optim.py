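"""First-order optimizers with their conventional default hyperparameters.

Defaults match the common deep-learning framework settings: SGD lr 0.01,
RMSprop lr 0.001 / rho 0.9, Adam lr 0.001 / beta1 0.9 / beta2 0.999.
State is keyed by position in the parameter list, which the network yields
in a stable order.
"""

from __future__ import annotations

import numpy as np


class Optimizer:
    name = "base"

    def step(self, params_and_grads: list[tuple[np.ndarray, np.ndarray]]) -> None:
        raise NotImplementedError

    def hyperparameters(self) -> dict[str, float]:
        return {
            k: v for k, v in vars(self).items() if isinstance(v, (int, float))
        }


class SGD(Optimizer):
    name = "sgd"

    def __init__(self, lr: float = 0.01, momentum: float = 0.0):
        self.lr = lr
        self.momentum = momentum
        self._vel: dict[int, np.ndarray] = {}

    def step(self, params_and_grads):
        for i, (p, g) in enumerate(params_and_grads):
            if self.momentum:
                v = self._vel.setdefault(i, np.zeros_like(p))
                v *= self.momentum
                v -= self.lr * g
                p += v
            else:
                p -= self.lr * g


class RMSprop(Optimizer):
    name = "rmsprop"

    def __init__(self, lr: float = 0.001, rho: float = 0.9, eps: float = 1e-7):
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._sq: dict[int, np.ndarray] = {}

    def step(self, params_and_grads):
        for i, (p, g) in enumerate(params_and_grads):
            s = self._sq.setdefault(i, np.zeros_like(p))
            s *= self.rho
            s += (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(s) + self.eps)


class Adam(Optimizer):
    name = "adam"

    def __init__(
        self,
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params_and_grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for i, (p, g) in enumerate(params_and_grads):
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


OPTIMIZERS = {"sgd": SGD, "rmsprop": RMSprop, "adam": Adam}
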