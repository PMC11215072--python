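"""Minimal reverse-mode automatic differentiation on numpy arrays.

This backbone provides exactly the operations needed by the volumetric
style-based generator, discriminator and inversion encoder: dense layers,
3x3x3 "same" convolutions, nearest-neighbour upsampling, average-pool
downsampling, leaky ReLU, softplus and the usual arithmetic with
broadcasting.  Everything is float32 and fully deterministic: given the
same parameters and inputs, forward and backward passes are bit-identical
across runs (numpy's einsum and reductions are deterministic on one CPU).

Volumes use the (N, C, D, H, W) layout throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the closure that routes gradients to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = grad.astype(np.float32)
        else:
            self.grad = self.grad + grad

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    def __neg__(self):
        return self * Tensor(np.float32(-1.0))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def square(self):
        return self * self

    def matmul(self, other: "Tensor") -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def sum(self):
        def bw(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(), (self,), bw)

    def mean(self):
        n = np.float32(self.data.size)

        def bw(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g / n, self.shape).copy())

        return self._make(self.data.mean(), (self,), bw)

    # -- nonlinearities ----------------------------------------------------

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, np.float32(1.0), np.float32(slope))

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def softplus(self):
        # numerically stable log(1 + e^x)
        out = np.logaddexp(np.float32(0.0), self.data).astype(np.float32)
        sig = 1.0 / (1.0 + np.exp(-self.data.astype(np.float64)))
        sig = sig.astype(np.float32)

        def bw(g):
            if self.requires_grad:
                self._accum(g * sig)

        return self._make(out, (self,), bw)

    # -- volumetric ops ----------------------------------------------------

    def conv3d(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """3x3x3 cross-correlation with 'same' zero padding.

        self: (N, C, D, H, W); weight: (O, C, 3, 3, 3); bias: (O,).
        """
        x, w = self.data, weight.data
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, (3, 3, 3), axis=(2, 3, 4))
        out = np.einsum("ncdhwijk,ocijk->nodhw", cols, w, optimize=True)
        out += bias.data[None, :, None, None, None]
        out = out.astype(np.float32)

        def bw(g):
            if weight.requires_grad:
                weight._accum(
                    np.einsum("ncdhwijk,nodhw->ocijk", cols, g, optimize=True)
                )
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3, 4)))
            if self.requires_grad:
                gp = np.pad(g, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
                gcols = np.lib.stride_tricks.sliding_window_view(
                    gp, (3, 3, 3), axis=(2, 3, 4)
                )
                wflip = w[:, :, ::-1, ::-1, ::-1]
                self._accum(
                    np.einsum("nodhwijk,ocijk->ncdhw", gcols, wflip, optimize=True)
                )

        return self._make(out, (self, weight, bias), bw)

    def avg_pool3d(self) -> "Tensor":
        """2x downsampling by block averaging (the 'filtered downsampling')."""
        n, c, d, h, w = self.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"avg_pool3d needs even spatial dims, got {(d, h, w)}")
        r = self.data.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = r.mean(axis=(3, 5, 7))

        def bw(g):
            if self.requires_grad:
                ge = (
                    np.repeat(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3), 2, axis=4)
                    / np.float32(8.0)
                )
                self._accum(ge)

        return self._make(out, (self,), bw)

    def upsample_nearest(self) -> "Tensor":
        """2x nearest-neighbour upsampling along D, H, W."""
        out = np.repeat(
            np.repeat(np.repeat(self.data, 2, axis=2), 2, axis=3), 2, axis=4
        )

        def bw(g):
            if self.requires_grad:
                n, c, d, h, w = g.shape
                r = g.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
                self._accum(r.sum(axis=(3, 5, 7)))

        return self._make(out, (self,), bw)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer over a flat list of Parameters."""

    def __init__(self, params, lr=1e-3, betas=(0.0, 0.99), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                np.float32
            )

    def state_arrays(self):
        return {"m": self.m, "v": self.v, "t": self.t}
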