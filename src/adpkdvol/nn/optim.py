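"""Rectified Adam and Lookahead optimizers.

RAdam rectifies the variance of the adaptive learning rate early in
training (falling back to momentum-SGD updates while the second-moment
estimate is unreliable, i.e. while the SMA length is below 5); Lookahead
maintains a slow copy of the weights and interpolates toward the fast
weights every ``k`` steps.  Used together they match the optimization
protocol of the segmentation training recipe.
"""
from __future__ import annotations

import numpy as np

__all__ = ["RAdam", "Lookahead"]


class RAdam:
    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.rho_inf = 2.0 / (1.0 - self.beta2) - 1.0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        t = self.t
        beta2_t = self.beta2**t
        rho_t = self.rho_inf - 2.0 * t * beta2_t / (1.0 - beta2_t)
        bias1 = 1.0 - self.beta1**t
        if rho_t >= 5.0:
            r_num = (rho_t - 4.0) * (rho_t - 2.0) * self.rho_inf
            r_den = (self.rho_inf - 4.0) * (self.rho_inf - 2.0) * rho_t
            rect = np.sqrt(r_num / r_den)
        else:
            rect = None
        for k, p in self.params.items():
            g = grads[k]
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            m_hat = self.m[k] / bias1
            if rect is not None:
                v_hat = np.sqrt(self.v[k] / (1.0 - beta2_t))
                p -= self.lr * rect * m_hat / (v_hat + self.eps)
            else:
                p -= self.lr * m_hat


class Lookahead:
    """Wraps a base optimizer; syncs slow weights every ``k`` steps."""

    def __init__(self, base: RAdam, k: int = 5, alpha: float = 0.5):
        if k < 1 or not (0.0 < alpha <= 1.0):
            raise ValueError("need k >= 1 and alpha in (0, 1]")
        self.base = base
        self.k = k
        self.alpha = alpha
        self._step_count = 0
        self.slow = {key: p.copy() for key, p in base.params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.base.step(grads)
        self._step_count += 1
        if self._step_count % self.k == 0:
            for key, p in self.base.params.items():
                self.slow[key] += self.alpha * (p - self.slow[key])
                p[...] = self.slow[key]
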