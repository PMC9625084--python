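"""Parameterized layers over the autodiff tensors."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d

__all__ = ["Layer", "Conv2D", "Dense", "Module"]

DTYPE = np.float32


class Layer:
    """Base class: a layer owns named parameter tensors."""

    def parameters(self) -> list[Tensor]:
        return [v for v in vars(self).values() if isinstance(v, Tensor)]

    def state(self) -> dict[str, np.ndarray]:
        return {
            k: v.data for k, v in vars(self).items() if isinstance(v, Tensor)
        }

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, arr in state.items():
            getattr(self, k).data = np.asarray(arr, dtype=DTYPE)


class Conv2D(Layer):
    """3x3 (by default) same-padding convolution with He-normal init."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, k: int = 3):
        fan_in = k * k * c_in
        std = np.sqrt(2.0 / fan_in)
        self.W = Tensor(
            rng.normal(0.0, std, size=(k, k, c_in, c_out)).astype(DTYPE),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.W, self.b)


class Dense(Layer):
    """Fully connected layer with He-normal init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / d_in)
        self.W = Tensor(
            rng.normal(0.0, std, size=(d_in, d_out)).astype(DTYPE), requires_grad=True
        )
        self.b = Tensor(np.zeros(d_out, dtype=DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.W) + self.b


class Module:
    """A container of layers; collects parameters and flat state dicts."""

    def layers(self) -> dict[str, Layer]:
        out: dict[str, Layer] = {}
        for name, val in vars(self).items():
            if isinstance(val, Layer):
                out[name] = val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Layer):
                        out[f"{name}.{i}"] = item
        return out

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for layer in self.layers().values():
            params.extend(layer.parameters())
        return params

    def state(self) -> dict[str, np.ndarray]:
        flat: dict[str, np.ndarray] = {}
        for lname, layer in self.layers().items():
            for pname, arr in layer.state().items():
                flat[f"{lname}/{pname}"] = arr
        return flat

    def load_state(self, flat: dict[str, np.ndarray]) -> None:
        layers = self.layers()
        for key, arr in flat.items():
            lname, pname = key.rsplit("/", 1)
            getattr(layers[lname], pname).data = np.asarray(arr, dtype=DTYPE)
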