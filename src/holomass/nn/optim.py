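"""Adaptive-moment optimizer with the AMSGrad correction."""

from __future__ import annotations

import ctypes
import ctypes.util

import numpy as np

from .tensor import Tensor

__all__ = ["Adam", "release_heap"]


def release_heap() -> None:
    """Return freed allocator memory to the OS (glibc malloc_trim).

    Training allocates and frees many medium-sized arrays per step; glibc
    retains the freed chunks, so resident memory otherwise grows without
    bound on long runs.  No-op on platforms without malloc_trim.
    """
    try:
        libc = ctypes.CDLL(ctypes.util.find_library("c") or "libc.so.6")
        libc.malloc_trim(0)
    except (OSError, AttributeError):
        pass


class Adam:
    """Adam with the AMSGrad variant (non-decreasing second-moment cap) on
    by default, matching the training scheme used for both networks."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        amsgrad: bool = True,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.amsgrad = amsgrad
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.vhat = [np.zeros_like(p.data) for p in params] if amsgrad else None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            if self.amsgrad:
                np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
                v = self.vhat[i]
            else:
                v = self.v[i]
            p.data = p.data - self.lr * (self.m[i] / b1t) / (
                np.sqrt(v / b2t) + self.eps
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
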