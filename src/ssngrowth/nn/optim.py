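"""AdamW and the warmup + cosine-annealing learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["AdamW", "warmup_cosine_lr"]


class AdamW:
    """Decoupled weight-decay Adam.

    ``betas[0]`` is the gradient momentum (0.9 as used for training),
    ``betas[1]`` the second-moment decay (standard 0.999); weight decay
    is applied directly to the parameters, not through the gradient.
    """

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.05):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def warmup_cosine_lr(epoch: float, *, base_lr: float = 5e-4, batch_size: int = 16,
                     epochs: int = 100, warmup_epochs: int = 5,
                     start_lr: float = 1e-5, min_lr: float = 0.0) -> float:
    """Learning rate at a (fractional) epoch position.

    Linear warmup from ``start_lr`` to the scaled peak
    ``base_lr * batch_size / 64`` over the first ``warmup_epochs``
    epochs, then cosine annealing down to ``min_lr`` at the final
    epoch.
    """
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    peak = base_lr * batch_size / 64.0
    if warmup_epochs > 0 and epoch < warmup_epochs:
        return start_lr + (peak - start_lr) * (epoch / warmup_epochs)
    if epochs <= warmup_epochs:
        return peak
    frac = (epoch - warmup_epochs) / (epochs - warmup_epochs)
    frac = min(max(frac, 0.0), 1.0)
    return min_lr + (peak - min_lr) * 0.5 * (1.0 + np.cos(np.pi * frac))
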