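"""Layer abstractions over the autodiff engine: parameters, linear/conv layers,
normalisation, and a Module container with named-parameter traversal and
state-dict (de)serialisation."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Tensor, conv3d

__all__ = ["Module", "Parameter", "Linear", "Conv3d", "LayerNorm",
           "InstanceNorm3d", "ModuleList"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container; submodules and parameters are discovered from
    instance attributes, in attribute definition order (deterministic)."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
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

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)[:3]} "
                           f"extra={sorted(extra)[:3]}")
        for k, p in params.items():
            if p.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules):
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, scale: float | None = None):
        s = scale if scale is not None else float(np.sqrt(2.0 / (d_in + d_out)))
        self.weight = Parameter(rng.normal(0.0, s, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv3d(Module):
    """'Same' 3-D convolution with an odd cubic kernel, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True):
        fan_in = c_in * kernel ** 3
        s = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(rng.normal(0.0, s, size=(c_out, c_in, kernel, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class LayerNorm(Module):
    """Normalisation over the trailing (channel) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xn = xc * ((var + self.eps) ** -0.5)
        return xn * self.gamma + self.beta


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalisation over the spatial axes of
    (B, C, D, H, W); the appropriate choice at batch size 1."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones((1, channels, 1, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1, 1)))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta
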