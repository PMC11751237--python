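"""Adam with classic L2 weight decay (decay folded into the gradient)."""

from __future__ import annotations

import numpy as np

from .modules import Parameter


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 4e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float32).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float32).copy() for v in state["v"]]
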