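"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps an
``ndarray``, records the operation that produced it, and ``backward()``
walks the tape in reverse topological order accumulating gradients.
Only the operations needed by the reconstruction network and the
differentiable training losses are implemented (elementwise arithmetic,
reductions, 2-D convolution / transposed convolution, batch
normalisation, slicing, concatenation and a fixed linear resampling).

Convolutions are evaluated as a short loop over kernel offsets, each
iteration a single large ``tensordot`` — fast in practice and
allocation-light compared with an explicit im2col buffer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables tape recording (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        o = self._wrap(other)
        out = self._make(self.data + o.data, (self, o), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g, o.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)

        def bw(g):
            self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        o = self._wrap(other)
        out = self._make(self.data * o.data, (self, o), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g * self.data, o.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._wrap(other)
        out = self._make(self.data / o.data, (self, o), None)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(-g * self.data / o.data**2, o.data.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out = self._make(self.data**p, (self,), None)

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = self._make(self.data[idx], (self,), None)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = bw
        return out

    # ------------------------------------------------------------- elementwise
    def exp(self):
        e = np.exp(self.data)
        out = self._make(e, (self,), None)

        def bw(g):
            self._accumulate(g * e)

        out._backward = bw
        return out

    def abs(self):
        out = self._make(np.abs(self.data), (self,), None)

        def bw(g):
            self._accumulate(g * np.sign(self.data))

        out._backward = bw
        return out

    def relu(self):
        mask = self.data > 0
        out = self._make(self.data * mask, (self,), None)

        def bw(g):
            self._accumulate(g * mask)

        out._backward = bw
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = self._make(r, (self,), None)

        def bw(g):
            self._accumulate(g * 0.5 / r)

        out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        mask = (self.data >= lo) & (self.data <= hi)
        out = self._make(np.clip(self.data, lo, hi), (self,), None)

        def bw(g):
            self._accumulate(g * mask)

        out._backward = bw
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)

        def bw(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = self._make(self.data.transpose(axes), (self,), None)

        def bw(g):
            self._accumulate(g.transpose(inv))

        out._backward = bw
        return out

    # ------------------------------------------------------------ convolutions
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, stride: int = 1,
               padding: int = 0):
        """2-D cross-correlation, ``x (N,C,H,W)  w (Co,Ci,kh,kw)``."""
        x = self.data
        w = weight.data
        n, ci, h, wd = x.shape
        co, ci2, kh, kw = w.shape
        if ci != ci2:
            raise ValueError(f"channel mismatch: input {ci} vs weight {ci2}")
        s, p = stride, padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - kh) // s + 1
        wo = (wd + 2 * p - kw) // s + 1
        out_data = np.zeros((n, ho, wo, co), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                patch = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                # (N,Ci,Ho,Wo) x (Co,Ci) -> (N,Ho,Wo,Co)
                out_data += np.tensordot(patch, w[:, :, i, j], axes=([1], [1]))
        out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
        if bias is not None:
            out_data += bias.data[None, :, None, None]
        parents = (self, weight) + ((bias,) if bias is not None else ())
        out = self._make(out_data, parents, None)

        def bw(g):
            gt = g.transpose(0, 2, 3, 1)  # (N,Ho,Wo,Co)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            need_x = self.requires_grad
            need_w = weight.requires_grad
            dxp = np.zeros_like(xp) if need_x else None
            dw = np.zeros_like(w) if need_w else None
            for i in range(kh):
                for j in range(kw):
                    patch = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
                    if need_w:
                        # (N,Ho,Wo,Co) x (N,Ci,Ho,Wo) -> (Co,Ci)
                        dw[:, :, i, j] = np.tensordot(
                            gt, patch, axes=([0, 1, 2], [0, 2, 3]))
                    if need_x:
                        # (N,Ho,Wo,Co) x (Co,Ci) -> (N,Ho,Wo,Ci)
                        dpatch = np.tensordot(gt, w[:, :, i, j], axes=([3], [0]))
                        dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                            dpatch.transpose(0, 3, 1, 2)
            if need_w:
                weight._accumulate(dw)
            if need_x:
                dx = dxp[:, :, p:p + h, p:p + wd] if p else dxp
                self._accumulate(dx)

        out._backward = bw
        return out

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor" = None,
                         stride: int = 2, padding: int = 1):
        """Transposed 2-D convolution, ``x (N,Ci,H,W)  w (Ci,Co,kh,kw)``.

        Output spatial size is ``(H-1)*stride - 2*padding + k`` (with the
        default 4x4 kernel, stride 2, padding 1: exactly 2H x 2W).
        """
        x = self.data
        w = weight.data
        n, ci, h, wd = x.shape
        ci2, co, kh, kw = w.shape
        if ci != ci2:
            raise ValueError(f"channel mismatch: input {ci} vs weight {ci2}")
        s, p = stride, padding
        ho = (h - 1) * s - 2 * p + kh
        wo = (wd - 1) * s - 2 * p + kw
        hp, wp = ho + 2 * p, wo + 2 * p
        outp = np.zeros((n, co, hp, wp), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                # scatter x * w[:, :, i, j] onto strided slices
                contrib = np.tensordot(x, w[:, :, i, j], axes=([1], [0]))
                outp[:, :, i:i + s * h:s, j:j + s * wd:s] += \
                    contrib.transpose(0, 3, 1, 2)
        out_data = outp[:, :, p:p + ho, p:p + wo]
        if bias is not None:
            out_data = out_data + bias.data[None, :, None, None]
        out_data = np.ascontiguousarray(out_data)
        parents = (self, weight) + ((bias,) if bias is not None else ())
        out = self._make(out_data, parents, None)

        def bw(g):
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2, 3)))
            gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p))) if p else g
            need_x = self.requires_grad
            need_w = weight.requires_grad
            dx = np.zeros_like(x) if need_x else None
            dw = np.zeros_like(w) if need_w else None
            for i in range(kh):
                for j in range(kw):
                    gslice = gp[:, :, i:i + s * h:s, j:j + s * wd:s]
                    if need_x:
                        dx += np.tensordot(gslice, w[:, :, i, j],
                                           axes=([1], [1])).transpose(0, 3, 1, 2)
                    if need_w:
                        dw[:, :, i, j] = np.tensordot(
                            x, gslice, axes=([0, 2, 3], [0, 2, 3]))
            if need_x:
                self._accumulate(dx)
            if need_w:
                weight._accumulate(dw)

        out._backward = bw
        return out

    def resample(self, my: np.ndarray, mx: np.ndarray):
        """Fixed linear resampling ``out = my @ x @ mx.T`` on the last two axes.

        ``my``/``mx`` are constant interpolation matrices, so this is a
        differentiable bilinear resize with precomputed weights.
        """
        out_data = np.einsum("ph,...hw,qw->...pq", my, self.data, mx,
                             optimize=True)
        out = self._make(out_data, (self,), None)

        def bw(g):
            self._accumulate(np.einsum("ph,...pq,qw->...hw", my, g, mx,
                                       optimize=True))

        out._backward = bw
        return out

    def batchnorm2d(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5,
                    mean=None, var=None):
        """Channel-wise normalisation over (N, H, W).

        When ``mean``/``var`` are given (inference with running statistics)
        they are treated as constants.
        """
        x = self.data
        use_batch = mean is None
        if use_batch:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out_data = gamma.data[None, :, None, None] * xhat + \
            beta.data[None, :, None, None]
        out = self._make(out_data, (self, gamma, beta), None)

        def bw(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gi = g * gamma.data[None, :, None, None]
                if use_batch:
                    m = x.shape[0] * x.shape[2] * x.shape[3]
                    dxhat_sum = gi.sum(axis=(0, 2, 3))
                    dxhat_dot = (gi * xhat).sum(axis=(0, 2, 3))
                    dx = (gi - (dxhat_sum[None, :, None, None] +
                                xhat * dxhat_dot[None, :, None, None]) / m) * \
                        inv[None, :, None, None]
                else:
                    dx = gi * inv[None, :, None, None]
                self._accumulate(dx)

        out._backward = bw
        return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = bw
    return out
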