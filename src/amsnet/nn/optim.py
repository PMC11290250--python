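"""Optimizers."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied directly to the weights (not folded into the
    gradient), following the decoupled formulation.  Biases, batch-norm
    affine parameters and other rank-<2 tensors are excluded from decay.
    """

    def __init__(self, model, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._params = list(model.named_parameters())
        self._m = [np.zeros_like(mod.params[k]) for _, mod, k in self._params]
        self._v = [np.zeros_like(mod.params[k]) for _, mod, k in self._params]
        self.t = 0

    def zero_grad(self) -> None:
        for _, mod, k in self._params:
            mod.grads[k][...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for i, (_, mod, k) in enumerate(self._params):
            g = mod.grads[k]
            p = mod.params[k]
            self._m[i] = self.beta1 * self._m[i] + (1 - self.beta1) * g
            self._v[i] = self.beta2 * self._v[i] + (1 - self.beta2) * g * g
            mhat = self._m[i] / bc1
            vhat = self._v[i] / bc2
            if self.weight_decay and p.ndim >= 2:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
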