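"""Stochastic gradient descent with classical momentum.

The optimizer holds one velocity buffer per parameter; ``reset()`` discards
them, which is how retraining after each injury step reinitializes the
optimizer state (a fresh ``SGD`` instance is equivalent).
"""

from __future__ import annotations

import numpy as np

from .network import Sequential

__all__ = ["SGD"]


class SGD:
    def __init__(self, network: Sequential, lr: float, momentum: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.network = network
        self.lr = lr
        self.momentum = momentum
        self._velocity: dict[tuple[str, str], np.ndarray] = {}

    def reset(self) -> None:
        self._velocity.clear()

    def step(self) -> None:
        for layer in self.network.layers:
            for key, grad in layer.grads.items():
                param = layer.params[key]
                vkey = (layer.name, key)
                if self.momentum:
                    v = self._velocity.get(vkey)
                    if v is None:
                        v = np.zeros_like(param)
                        self._velocity[vkey] = v
                    v *= self.momentum
                    v += grad
                    param -= (self.lr * v).astype(param.dtype)
                else:
                    param -= (self.lr * grad).astype(param.dtype)
            layer.grads = {}
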