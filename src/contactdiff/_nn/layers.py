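"""Layers and the Adam optimizer for the NumPy autodiff engine."""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = ["Module", "Conv2d", "Linear", "GroupNorm", "ModuleList", "Adam"]


class Module:
    """Base class; submodules and parameters are discovered via attributes."""

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Parameter]]:
        for name, attr in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                yield full, attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(prefix=full + ".")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=np.float32).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        self.items = list(modules)

    def append(self, m):
        self.items.append(m)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)


class Conv2d(Module):
    """3x3 (or 1x1 / strided) convolution with Kaiming-uniform init."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1,
                 padding: Optional[int] = None, zero_init: bool = False,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        if zero_init:
            w = np.zeros((cout, cin, kernel, kernel))
        else:
            bound = np.sqrt(1.0 / (cin * kernel * kernel))
            w = rng.uniform(-bound, bound, size=(cout, cin, kernel, kernel))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding)


class Linear(Module):
    def __init__(self, din: int, dout: int, zero_init: bool = False,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        if zero_init:
            w = np.zeros((din, dout))
        else:
            bound = np.sqrt(1.0 / din)
            w = rng.uniform(-bound, bound, size=(din, dout))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(dout))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class GroupNorm(Module):
    """Group normalization over (B, C, H, W) with learned gain and bias."""

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        if channels % groups:
            raise ValueError("channels must divide into groups")
        self.groups = groups
        self.channels = channels
        self.eps = eps
        self.gain = Parameter(np.ones((1, channels, 1, 1)))
        self.bias = Parameter(np.zeros((1, channels, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        return x.groupnorm(self.gain, self.bias, self.groups, self.eps)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: List[Parameter], lr: float = 1e-4,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
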