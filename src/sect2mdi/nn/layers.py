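"""Layer primitives built on the autodiff tensor."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Parameter, Tensor

__all__ = ["Module", "Linear", "LayerNorm", "ModuleList"]


class Module:
    """Parameter container with recursive discovery, torch-flavoured."""

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                yield p

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)

    def append(self, module: Module) -> None:
        self.items.append(module)


class Linear(Module):
    """Affine layer with Glorot-normal weight initialization.

    Glorot scaling keeps activation and gradient magnitudes comparable
    across a deep stack, which matters for regression heads: a fixed small
    init starves downstream-of-small-weights subnetworks of gradient early
    in training.
    """

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 init_scale: float | None = None):
        scale = (np.sqrt(2.0 / (in_features + out_features))
                 if init_scale is None else init_scale)
        self.weight = Parameter(scale * rng.standard_normal((in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.eps) * self.gamma + self.beta
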