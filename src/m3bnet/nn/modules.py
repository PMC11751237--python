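"""Module system: parameter containers with state-dict (de)serialization."""

from __future__ import annotations

import hashlib

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        self.requires_grad = True  # parameters track gradients even under no_grad construction


class Module:
    """Base class; submodules and parameters are discovered from __dict__."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{full}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def weight_hash(self) -> str:
        """SHA-256 over all parameters, in name order — used by freeze checks."""
        h = hashlib.sha256()
        for name, p in sorted(self.named_parameters()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for the conv+relu stacks used here
        self.weight = Parameter(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class InstanceNorm2d(Module):
    def __init__(self, channels: int, affine: bool = True, eps: float = 1e-5):
        self.eps = eps
        self.weight = Parameter(np.ones(channels)) if affine else None
        self.bias = Parameter(np.zeros(channels)) if affine else None

    def forward(self, x: Tensor) -> Tensor:
        y = F.instance_norm(x, eps=self.eps)
        if self.weight is not None:
            c = self.weight.data.shape[0]
            y = y * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)
        return y


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)
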