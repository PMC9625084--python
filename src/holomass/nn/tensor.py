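"""Compact reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the regression networks need — dense and
3x3 same-padding convolutions (via im2col and BLAS matmul), 2x2 max-pooling
and nearest-neighbour upsampling, ReLU/sigmoid/softmax, broadcasting
arithmetic, reductions, and the two losses (binary cross-entropy, masked
mean absolute error).  Gradients flow through a taped graph released after
each backward pass; everything is single-threaded numpy and fully
deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "split_last",
    "conv2d",
    "maxpool2",
    "upsample2",
    "softmax",
    "bce",
]


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph machinery ----------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor into the graph leaves.

        Iterative topological sort: a recursive closure here would be
        self-referential and keep the whole taped graph (activations and
        gradients) alive until the cycle collector runs.
        """
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:  # interior node: propagate and release
                t._backward(t.grad)
                t._parents = ()
                t._backward = None
                if t is not self:
                    t.grad = None  # leaf (parameter) gradients persist

    def _accum(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def back(g, a=self, b=other, sa=self.data.shape, sb=other.data.shape):
            if a.requires_grad:
                a._accum(_unbroadcast(g, sa))
            if b.requires_grad:
                b._accum(_unbroadcast(g, sb))

        return Tensor(out_data, parents=(self, other), backward=back)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def back(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(out_data, parents=(self, other), backward=back)

    def __neg__(self):
        def back(g, a=self):
            a._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=back)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data

        def back(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor(out_data, parents=(self, other), backward=back)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape

        def back(g, a=self):
            a._accum(g.reshape(orig))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=back)

    # -- nonlinearities -------------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def back(g, a=self):
            a._accum(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=back)

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

        def back(g, a=self):
            a._accum(g * y * (1.0 - y))

        return Tensor(y, parents=(self,), backward=back)

    def abs(self) -> "Tensor":
        s = np.sign(self.data)

        def back(g, a=self):
            a._accum(g * s)

        return Tensor(np.abs(self.data), parents=(self,), backward=back)

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g, a=self, ax=axis, kd=keepdims):
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape).astype(a.data.dtype, copy=False))

        return Tensor(out_data, parents=(self,), backward=back)

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g, ts=tuple(tensors), ax=axis, sp=splits):
        for t, piece in zip(ts, np.split(g, sp, axis=ax)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor(out_data, parents=tuple(tensors), backward=back)


def split_last(t: Tensor, sizes: list[int]) -> list[Tensor]:
    """Split along the last axis into chunks of the given sizes."""
    splits = np.cumsum(sizes)[:-1]
    pieces = np.split(t.data, splits, axis=-1)
    offsets = np.concatenate([[0], splits])
    outs = []
    for i, piece in enumerate(pieces):
        def back(g, t=t, lo=int(offsets[i]), w=sizes[i]):
            full = np.zeros_like(t.data)
            full[..., lo : lo + w] = g
            t._accum(full)

        outs.append(Tensor(piece, parents=(t,), backward=back))
    return outs


def conv2d(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Same-padding stride-1 convolution; NHWC input, (kh, kw, Cin, Cout) kernel."""
    N, H, Wd, C = x.data.shape
    kh, kw, _, F = W.data.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # win: (N, H, Wd, C, kh, kw) -> (N*H*Wd, kh*kw*C)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        N * H * Wd, kh * kw * C
    )
    Wmat = W.data.reshape(kh * kw * C, F)
    out_data = (cols @ Wmat + b.data).reshape(N, H, Wd, F)

    def back(g, x=x, W=W, b=b, cols=cols, Wmat=Wmat):
        gf = g.reshape(-1, g.shape[-1])
        if b.requires_grad:
            b._accum(gf.sum(axis=0))
        if W.requires_grad:
            W._accum((cols.T @ gf).reshape(W.data.shape))
        if x.requires_grad:
            dcols = (gf @ Wmat.T).reshape(N, H, Wd, kh, kw, C)
            dxp = np.zeros((N, H + 2 * ph, Wd + 2 * pw, C), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i : i + H, j : j + Wd, :] += dcols[:, :, :, i, j, :]
            x._accum(dxp[:, ph : ph + H, pw : pw + Wd, :])

    return Tensor(out_data, parents=(x, W, b), backward=back)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2 (spatial dims must be even)."""
    N, H, W, C = x.data.shape
    xr = x.data.reshape(N, H // 2, 2, W // 2, 2, C)
    xt = np.ascontiguousarray(xr.transpose(0, 1, 3, 5, 2, 4)).reshape(
        N, H // 2, W // 2, C, 4
    )
    idx = np.argmax(xt, axis=-1)
    out_data = np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]

    def back(g, x=x, idx=idx):
        gt = np.zeros((N, H // 2, W // 2, C, 4), dtype=g.dtype)
        np.put_along_axis(gt, idx[..., None], g[..., None], axis=-1)
        gx = (
            gt.reshape(N, H // 2, W // 2, C, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(N, H, W, C)
        )
        x._accum(gx)

    return Tensor(out_data, parents=(x,), backward=back)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out_data = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def back(g, x=x):
        N, H2, W2, C = g.shape
        x._accum(g.reshape(N, H2 // 2, 2, W2 // 2, 2, C).sum(axis=(2, 4)))

    return Tensor(out_data, parents=(x,), backward=back)


def softmax(x: Tensor, axis: int) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    y = e / e.sum(axis=axis, keepdims=True)

    def back(g, x=x, ax=axis):
        dot = (g * y).sum(axis=ax, keepdims=True)
        x._accum(y * (g - dot))

    return Tensor(y, parents=(x,), backward=back)


def bce(p: Tensor, target: np.ndarray, eps: float = 1e-7, pos_weight: float = 1.0) -> Tensor:
    """Mean binary cross-entropy of probabilities ``p`` against 0/1 targets.

    ``pos_weight`` multiplies the positive-class term, countering class
    imbalance (e.g. sparse foreground in segmentation maps).
    """
    pc = np.clip(p.data, eps, 1.0 - eps)
    out = -np.mean(
        pos_weight * target * np.log(pc) + (1.0 - target) * np.log(1.0 - pc)
    )

    def back(g, p=p, pc=pc):
        dp = (-(pos_weight * target / pc) + (1.0 - target) / (1.0 - pc)) / pc.size
        p._accum(g * dp)

    return Tensor(np.asarray(out), parents=(p,), backward=back)
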