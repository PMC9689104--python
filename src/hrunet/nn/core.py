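"""Minimal NumPy layer framework with explicit forward/backward passes.

Every layer caches what its backward pass needs only when run with
``training=True``; inference at large image sizes therefore stays
memory-light.  All parameters are float32.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Module:
    """Base class: a differentiable map of (B, C, H, W) feature grids."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)

    # -- parameter traversal ------------------------------------------------
    def named_params(self, prefix: str = ""):
        """Yield (dotted-name, Param) pairs, recursing into child modules."""
        for attr, obj in vars(self).items():
            name = f"{prefix}{attr}" if prefix else attr
            if isinstance(obj, Param):
                yield name, obj
            elif isinstance(obj, Module):
                yield from obj.named_params(prefix=name + ".")
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        yield from item.named_params(prefix=f"{name}.{i}.")

    def named_modules(self, prefix: str = ""):
        """Yield (dotted-name, Module) pairs, depth-first, self excluded."""
        for attr, obj in vars(self).items():
            name = f"{prefix}{attr}" if prefix else attr
            if isinstance(obj, Module):
                yield name, obj
                yield from obj.named_modules(prefix=name + ".")
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item
                        yield from item.named_modules(prefix=f"{name}.{i}.")

    def params(self):
        for _, p in self.named_params():
            yield p

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
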