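"""Nesterov-accelerated adaptive moment estimation (Nadam).

Adam with the momentum term replaced by a Nesterov look-ahead, using the
momentum schedule ``mu_t = beta_1 * (1 - 0.5 * 0.96**(t * schedule_decay))``
so the effective momentum warms up over the first updates.  Matches the
classic Keras formulation, whose hyperparameter quintuple (learning rate,
beta_1, beta_2, epsilon, schedule decay) this package adopts as defaults.
"""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["Nadam"]


class Nadam:
    def __init__(
        self,
        params: list[Parameter],
        learning_rate: float = 0.002,
        beta_1: float = 0.9,
        beta_2: float = 0.999,
        epsilon: float = 1e-8,
        schedule_decay: float = 0.004,
    ):
        if min(learning_rate, beta_1, beta_2, epsilon, schedule_decay) <= 0:
            raise ValueError("all Nadam rates must be positive")
        self.params = params
        self.lr, self.b1, self.b2 = learning_rate, beta_1, beta_2
        self.eps, self.sd = epsilon, schedule_decay
        self.t = 0
        self.m_schedule = 1.0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def _mu(self, t: int) -> float:
        return self.b1 * (1.0 - 0.5 * 0.96 ** (t * self.sd))

    def step(self) -> None:
        self.t += 1
        mu_t, mu_next = self._mu(self.t), self._mu(self.t + 1)
        self.m_schedule *= mu_t
        m_schedule_next = self.m_schedule * mu_next
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            g_prime = g / (1.0 - self.m_schedule)
            m[:] = self.b1 * m + (1.0 - self.b1) * g
            m_prime = m / (1.0 - m_schedule_next)
            v[:] = self.b2 * v + (1.0 - self.b2) * g * g
            v_prime = v / (1.0 - self.b2 ** self.t)
            m_bar = (1.0 - mu_t) * g_prime + mu_next * m_prime
            p.value -= self.lr * m_bar / (np.sqrt(v_prime) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[:] = 0.0
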