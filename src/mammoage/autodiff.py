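"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the substrate for the multi-view age-estimation network: a small
tape-based engine supporting exactly the operations the model needs
(dense/convolutional layers, multi-head attention arithmetic, softmax,
reductions) plus an Adam optimizer.  Everything is float64, which keeps
finite-difference gradient checks tight on CPU.

Design notes
------------
* A :class:`Tensor` wraps an ``ndarray`` and records its parents and a
  closure that accumulates gradients into them.  ``backward()`` runs the
  tape in reverse topological order.
* Broadcasting is supported in the elementwise ops; gradients are
  un-broadcast by summing over expanded axes.
* Convolution is implemented by ``sliding_window_view`` patches and a
  matmul; the input gradient is scattered back with nine strided adds
  rather than a python-level pixel loop.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "depthwise_conv2d", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- elementwise ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad)
            if other.requires_grad:
                other._accum(out.grad)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * other.data)
            if other.requires_grad:
                other._accum(out.grad * self.data)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * e * self.data ** (e - 1.0))

        return self._make(self.data ** e, (self,), backward)

    def exp(self):
        data = np.exp(self.data)

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * data)

        return self._make(data, (self,), backward)

    def log(self):
        def backward(out):
            if self.requires_grad:
                self._accum(out.grad / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def relu(self):
        mask = self.data > 0

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad * mask)

        return self._make(self.data * mask, (self,), backward)

    # -- shape ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def backward(out):
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(out):
            if self.requires_grad:
                grad = np.zeros_like(self.data)
                np.add.at(grad, idx, out.grad)
                self._accum(grad)

        return self._make(self.data[idx], (self,), backward)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(out):
            if not self.requires_grad:
                return
            grad = out.grad
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accum(np.broadcast_to(grad, self.data.shape))

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- linear algebra -------------------------------------------------
    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)

        def backward(out):
            if self.requires_grad:
                ga = np.matmul(out.grad, np.swapaxes(other.data, -1, -2))
                self._accum(ga)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), out.grad)
                other._accum(gb)

        return self._make(np.matmul(self.data, other.data), (self, other), backward)

    __matmul__ = matmul

    # -- composites ------------------------------------------------------
    def softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1) -> "Tensor":
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()

    # -- autodiff driver -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(out):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


# ---------------------------------------------------------------------------
# Convolution primitives
# ---------------------------------------------------------------------------

def _patches(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Return (padded input, strided view (B, C, Ho, Wo, kh, kw))."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    return x, win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    ``weight`` has shape (out_channels, in_channels, kh, kw).
    """
    B, C, H, W = x.data.shape
    O, Ci, kh, kw = weight.data.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, weight expects {Ci}")
    xp, pat = _patches(x.data, kh, kw, stride, pad)
    Ho, Wo = pat.shape[2], pat.shape[3]
    # (B, Ho, Wo, C*kh*kw) @ (C*kh*kw, O)
    col = pat.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho, Wo, C * kh * kw)
    wmat = weight.data.reshape(O, C * kh * kw)
    out = col @ wmat.T  # (B, Ho, Wo, O)
    out = out.transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(node):
        g = node.grad  # (B, O, Ho, Wo)
        gcol = g.transpose(0, 2, 3, 1)  # (B, Ho, Wo, O)
        if weight.requires_grad:
            gw = np.einsum("bijo,bijk->ok", gcol, col, optimize=True)
            weight._accum(gw.reshape(O, C, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcol = gcol @ wmat  # (B, Ho, Wo, C*kh*kw)
            dcol = dcol.reshape(B, Ho, Wo, C, kh, kw)
            gx = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += \
                        dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            x._accum(gx)

    return Tensor._make(out, parents, backward)


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 1, pad: int = 1) -> Tensor:
    """Depthwise 2-D convolution: one (kh, kw) filter per channel.

    ``weight`` has shape (channels, kh, kw).
    """
    B, C, H, W = x.data.shape
    Cw, kh, kw = weight.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weight expects {Cw}")
    xp, pat = _patches(x.data, kh, kw, stride, pad)  # (B,C,Ho,Wo,kh,kw)
    Ho, Wo = pat.shape[2], pat.shape[3]
    out = np.einsum("bcijkl,ckl->bcij", pat, weight.data, optimize=True)
    if bias is not None:
        out = out + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(node):
        g = node.grad  # (B, C, Ho, Wo)
        if weight.requires_grad:
            weight._accum(np.einsum("bcij,bcijkl->ckl", g, pat, optimize=True))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + Ho * stride:stride, j:j + Wo * stride:stride] += \
                        g * weight.data[None, :, i, j, None, None]
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            x._accum(gx)

    return Tensor._make(out, parents, backward)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the usual bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
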