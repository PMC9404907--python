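"""ADAM optimizer over a flat list of (params, grads) dicts."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adaptive-moment stochastic gradient descent.

    Standard bias-corrected first/second moment estimates; operates in
    place on the layer parameter dicts it is constructed with.
    """

    def __init__(self, layers, learning_rate: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        self.layers = [ly for ly in layers if ly.params]
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
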