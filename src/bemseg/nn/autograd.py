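"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations that
produced it; :meth:`Tensor.backward` walks the tape in reverse topological
order accumulating gradients.  Only the handful of ops needed by the 3D
U-Net family live here: 3D convolution, 2x max-pooling, trilinear 2x
upsampling, instance normalization, leaky ReLU and channel concatenation.

Activations use layout ``(C, X, Y, Z)`` with an implicit batch of one — the
batch size the volumetric networks train with anyway.
"""

from __future__ import annotations

from typing import Callable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "Tensor",
    "conv3d",
    "max_pool3d",
    "upsample3d",
    "instance_norm",
    "leaky_relu",
    "concat",
    "no_grad",
    "backward",
]

_grad_enabled = True


class no_grad:
    """Context manager that suspends tape recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


class Tensor:
    """A node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: Tuple["Tensor", ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray):
        """Backpropagate ``d(loss)/d(self) = grad`` through the tape."""
        backward([self], [grad])


def backward(outputs: Sequence["Tensor"], grads: Sequence[np.ndarray]) -> None:
    """Joint backward pass seeding several output tensors at once.

    Networks with two segmentation heads share most of the tape; seeding
    both heads in a single reverse sweep propagates each shared node exactly
    once.
    """
    topo: List[Tensor] = []
    seen = set()

    def visit(t: Tensor):
        if id(t) in seen:
            return
        seen.add(id(t))
        for p in t._parents:
            visit(p)
        topo.append(t)

    for out, g in zip(outputs, grads):
        visit(out)
        out._accumulate(np.asarray(g, dtype=np.float32))
    for t in reversed(topo):
        if t._backward is not None and t.grad is not None:
            t._backward()


def _node(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _corr3(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padding cross-correlation: x (Ci,X,Y,Z), w (Co,Ci,k,k,k)."""
    k = w.shape[-1]
    p = k // 2
    if p:
        x = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    view = np.lib.stride_tricks.sliding_window_view(x, (k, k, k), axis=(1, 2, 3))
    # view: (Ci, X, Y, Z, k, k, k) -> contract Ci,k,k,k against w
    return np.tensordot(w, view, axes=([1, 2, 3, 4], [0, 4, 5, 6]))


def conv3d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """3D convolution, stride 1, zero same-padding, odd kernel."""
    out = _corr3(x.data, weight.data) + bias.data[:, None, None, None]

    def backward():
        g = node.grad
        k = weight.data.shape[-1]
        p = k // 2
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(1, 2, 3)))
        if weight.requires_grad:
            xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p))) if p else x.data
            view = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
            # dW[co,ci,a,b,c] = sum_xyz g[co,xyz] * x[ci, xyz+off]
            dw = np.tensordot(g, view, axes=([1, 2, 3], [1, 2, 3]))
            weight._accumulate(dw)
        if x.requires_grad or x._parents:
            wf = weight.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            x._accumulate(_corr3(g, wf))

    node = _node(out, (x, weight, bias), backward)
    return node


def max_pool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling; spatial extents must be even."""
    C, X, Y, Z = x.data.shape
    if X % 2 or Y % 2 or Z % 2:
        raise ValueError(f"max_pool3d needs even extents, got {(X, Y, Z)}")
    r = x.data.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2)
    out = r.max(axis=(2, 4, 6))

    def backward():
        g = node.grad
        mask = r == out[:, :, None, :, None, :, None]
        cnt = mask.sum(axis=(2, 4, 6), keepdims=True)
        gx = mask * (g[:, :, None, :, None, :, None] / cnt)
        x._accumulate(gx.reshape(C, X, Y, Z))

    node = _node(out, (x,), backward)
    return node


def _upsample_axis_weights(n_out: int, n_in: int):
    # half-pixel-center linear interpolation (matches common resize semantics)
    coord = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    i0 = np.clip(np.floor(coord).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    w1 = np.clip(coord - np.floor(coord), 0.0, 1.0).astype(np.float32)
    w1[coord < 0] = 0.0
    return i0, i1, w1


def upsample3d(x: Tensor, factor: int = 2) -> Tensor:
    """Trilinear upsampling by an integer factor (separable per axis)."""
    plans = [
        _upsample_axis_weights(n * factor, n) for n in x.data.shape[1:]
    ]

    def interp(arr):
        for ax, (i0, i1, w1) in enumerate(plans, start=1):
            a0 = np.take(arr, i0, axis=ax)
            a1 = np.take(arr, i1, axis=ax)
            sh = [1] * arr.ndim
            sh[ax] = len(w1)
            w = w1.reshape(sh)
            arr = a0 * (1 - w) + a1 * w
        return arr

    out = interp(x.data)

    def backward():
        g = node.grad
        for ax in range(len(plans), 0, -1):  # transpose ops in reverse order
            i0, i1, w1 = plans[ax - 1]
            n_in = x.data.shape[ax]
            sh = [1] * g.ndim
            sh[ax] = len(w1)
            w = w1.reshape(sh)
            shape = list(g.shape)
            shape[ax] = n_in
            acc = np.zeros(shape, dtype=np.float32)
            gm = np.moveaxis(acc, ax, 0)
            np.add.at(gm, i0, np.moveaxis(g * (1 - w), ax, 0))
            np.add.at(gm, i1, np.moveaxis(g * w, ax, 0))
            g = acc
        x._accumulate(g)

    node = _node(out, (x,), backward)
    return node


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes, with affine params."""
    ax = (1, 2, 3)
    mu = x.data.mean(axis=ax, keepdims=True)
    var = x.data.var(axis=ax, keepdims=True)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * ivar
    gm = gamma.data[:, None, None, None]
    out = gm * xhat + beta.data[:, None, None, None]

    def backward():
        g = node.grad
        m = x.data[0].size  # voxels per channel
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=ax))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=ax))
        if x.requires_grad or x._parents:
            dxhat = g * gm
            t1 = dxhat.sum(axis=ax, keepdims=True)
            t2 = (dxhat * xhat).sum(axis=ax, keepdims=True)
            dx = (dxhat - (t1 + xhat * t2) / m) * ivar
            x._accumulate(dx.astype(np.float32))

    node = _node(out, (x, gamma, beta), backward)
    return node


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    out = np.where(x.data > 0, x.data, slope * x.data)

    def backward():
        g = node.grad
        x._accumulate(np.where(x.data > 0, g, slope * g))

    node = _node(out, (x,), backward)
    return node


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis (skip connections)."""
    out = np.concatenate([a.data, b.data], axis=0)
    na = a.data.shape[0]

    def backward():
        g = node.grad
        a._accumulate(g[:na])
        b._accumulate(g[na:])

    node = _node(out, (a, b), backward)
    return node
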