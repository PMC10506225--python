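"""Adam optimizer over a named collection of parameter arrays."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """Adam with the usual bias-corrected first/second moment estimates."""

    def __init__(
        self,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> dict:
        """Return updated copies of ``params`` given aligned gradients."""
        self.t += 1
        out = {}
        for name, value in params.items():
            g = np.asarray(grads[name], dtype=float)
            m = self._m.get(name, np.zeros_like(g))
            v = self._v.get(name, np.zeros_like(g))
            m = self.beta1 * m + (1 - self.beta1) * g
            v = self.beta2 * v + (1 - self.beta2) * g * g
            self._m[name] = m
            self._v[name] = v
            m_hat = m / (1 - self.beta1**self.t)
            v_hat = v / (1 - self.beta2**self.t)
            out[name] = value - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
        return out
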