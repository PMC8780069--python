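"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package targets CPU-only environments without a deep-learning framework,
so the differentiable layers (residual encoding, suppression masks, factorized
bilinear fusion, convolutions) are built on this small tape-based engine.
Only the operations the model needs are implemented; everything computes in
the dtype of its inputs, so float64 can be used for finite-difference checks
and float32 for training.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "as_tensor", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from length 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d array that records the operations applied to it.

    ``backward()`` accumulates gradients into ``.grad`` of every tensor in the
    graph that has ``requires_grad`` set (directly or through a parent).
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    # -------------------------------------------------------------- autodiff
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ----------------------------------------------------------- elementwise
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data * other.data), other.data.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bwd
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bwd
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / val)

        out._backward = bwd
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bwd
        return out

    def soft_threshold(self, lam: float):
        """sign(x) * max(|x| - lam, 0), with subgradient 0 in the dead zone."""
        mask = np.abs(self.data) > lam
        out = Tensor(np.sign(self.data) * np.maximum(np.abs(self.data) - lam, 0.0),
                     _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bwd
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bwd
        return out

    # --------------------------------------------------------- linear algebra
    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    # ----------------------------------------------------------- convolution
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D cross-correlation. self: (B,C,H,W), weight: (O,C,KH,KW)."""
        x, w = self.data, weight.data
        B, C, H, W = x.shape
        O, _, KH, KW = w.shape
        s, p = stride, padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (KH, KW), axis=(2, 3))[:, :, ::s, ::s]
        OH, OW = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B, OH * OW, C * KH * KW)
        wmat = w.reshape(O, C * KH * KW)
        val = cols @ wmat.T
        if bias is not None:
            val = val + bias.data
        out = Tensor(val.reshape(B, OH, OW, O).transpose(0, 3, 1, 2),
                     _parents=(self, weight) + (() if bias is None else (bias,)))

        def bwd(g):
            gflat = g.transpose(0, 2, 3, 1).reshape(B, OH * OW, O)
            if bias is not None and bias.requires_grad:
                bias._accumulate(gflat.sum(axis=(0, 1)))
            if weight.requires_grad:
                gw = np.einsum("bpo,bpk->ok", gflat, cols)
                weight._accumulate(gw.reshape(w.shape))
            if self.requires_grad:
                gcols = (gflat @ wmat).reshape(B, OH, OW, C, KH, KW)
                gxp = np.zeros_like(xp)
                for kh in range(KH):
                    for kw in range(KW):
                        gxp[:, :, kh:kh + s * OH:s, kw:kw + s * OW:s] += \
                            gcols[:, :, :, :, kh, kw].transpose(0, 3, 1, 2)
                self._accumulate(gxp[:, :, p:p + H, p:p + W] if p else gxp)

        out._backward = bwd
        return out

    def max_pool2d(self, kernel: int, stride: int, padding: int = 0):
        x = self.data
        B, C, H, W = x.shape
        k, s, p = kernel, stride, padding
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        else:
            xp = x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        OH, OW = win.shape[2], win.shape[3]
        flat = win.reshape(B, C, OH, OW, k * k)
        arg = flat.argmax(axis=-1)
        out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0],
                     _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            gxp = np.zeros(xp.shape, dtype=x.dtype)
            kh, kw = np.divmod(arg, k)
            bi, ci, oi, oj = np.indices(arg.shape)
            np.add.at(gxp, (bi, ci, oi * s + kh, oj * s + kw), g)
            self._accumulate(gxp[:, :, p:p + H, p:p + W] if p else gxp)

        out._backward = bwd
        return out

    def avg_pool2d(self, kernel: int, stride: int | None = None):
        """Non-overlapping average pooling (kernel == stride)."""
        if stride is not None and stride != kernel:
            raise NotImplementedError("avg_pool2d supports kernel == stride only")
        k = kernel
        B, C, H, W = self.data.shape
        if H % k or W % k:
            raise ValueError(f"spatial size ({H},{W}) not divisible by pool {k}")
        return (self.reshape(B, C, H // k, k, W // k, k).mean(axis=(3, 5)))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bwd
    return out
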