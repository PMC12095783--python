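"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the computational core used by the segmentation and feature
networks: a :class:`Tensor` wraps an ``ndarray``, records the operations
applied to it, and :meth:`Tensor.backward` walks the tape in reverse
topological order accumulating gradients.  The op set is exactly what
the networks in this package need — elementwise arithmetic, matmul,
conv2d (implemented as a sum of shifted-slice contractions), pooling,
nearest-neighbour upsampling, concatenation, reductions, ReLU/sigmoid,
softmax and the stable log-softmax cross-entropy.

Shapes follow the (N, C, H, W) convention throughout.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with gradient tracking."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] = lambda: None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for child in node._prev:
                    stack.append((child, False))

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=float)
        for node in reversed(topo):
            node._backward()
        # break the closure<->node reference cycles so intermediate
        # activations free by refcount (one-shot backward is all we need)
        for node in topo:
            node._backward = lambda: None
            node._prev = ()

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad)
        out._prev = (self, other)

        def backward() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad)
        out._prev = (self, other)

        def backward() -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) * self**-1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, self.requires_grad)
        out._prev = (self,)

        def backward() -> None:
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad)
        out._prev = (self, other)

        def backward() -> None:
            if self.requires_grad:
                g = out.grad @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accum(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    # -- nonlinearities ----------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad)
        out._prev = (self,)

        def backward() -> None:
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad)
        out._prev = (self,)

        def backward() -> None:
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad)
        out._prev = (self,)

        def backward() -> None:
            if self.requires_grad:
                self._accum(out.grad * e)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad)
        out._prev = (self,)

        def backward() -> None:
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = backward
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        out._prev = (self,)

        def backward() -> None:
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a % self.ndim] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Max along one axis; gradient flows to the first maximum."""
        ax = axis % self.ndim
        idx = np.argmax(self.data, axis=ax)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, ax), ax)
        if not keepdims:
            out_data = np.squeeze(out_data, ax)
        out = Tensor(out_data, self.requires_grad)
        out._prev = (self,)

        def backward() -> None:
            if not self.requires_grad:
                return
            g = out.grad if keepdims else np.expand_dims(out.grad, ax)
            scatter = np.zeros_like(self.data)
            np.put_along_axis(scatter, np.expand_dims(idx, ax), g, ax)
            self._accum(scatter)

        out._backward = backward
        return out

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        out._prev = (self,)

        def backward() -> None:
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = backward
        return out

    def transpose(self, *axes: int) -> "Tensor":
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        out = Tensor(self.data.transpose(*axes), self.requires_grad)
        out._prev = (self,)

        def backward() -> None:
            if self.requires_grad:
                self._accum(out.grad.transpose(np.argsort(axes)))

        out._backward = backward
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], self.requires_grad)
        out._prev = (self,)

        def backward() -> None:
            if self.requires_grad:
                scatter = np.zeros_like(self.data)
                np.add.at(scatter, key, out.grad)
                self._accum(scatter)

        out._backward = backward
        return out


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    """Concatenate along ``axis`` with gradient routing back to parts."""
    tensors = list(tensors)
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
    )
    out._prev = tuple(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward() -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant, no grad
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) on (N, C, H, W) input.

    ``w`` has shape (C_out, C_in, kh, kw).  Implemented as im2col plus
    a single dense matmul so both passes run through BLAS.
    """
    from numpy.lib.stride_tricks import sliding_window_view

    N, C, H, W = x.shape
    Cout, Cin, kh, kw = w.shape
    if Cin != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1

    # (N, C, Ho, Wo, kh, kw) view -> (N*Ho*Wo, C*kh*kw) matrix
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * kh * kw
    )
    w_mat = w.data.reshape(Cout, C * kh * kw)
    out_data = (cols @ w_mat.T).reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)

    out = Tensor(out_data, x.requires_grad or w.requires_grad
                 or (b is not None and b.requires_grad))
    out._prev = (x, w) if b is None else (x, w, b)

    def backward() -> None:
        g_mat = np.ascontiguousarray(out.grad.transpose(0, 2, 3, 1)).reshape(
            N * Ho * Wo, Cout
        )
        if w.requires_grad:
            w._accum((g_mat.T @ cols).reshape(w.shape))
        if x.requires_grad:
            dcols = (g_mat @ w_mat).reshape(N, Ho, Wo, C, kh, kw)
            dxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    dxp[:, :, ki : ki + stride * Ho : stride,
                        kj : kj + stride * Wo : stride] += \
                        dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)
        if b is not None and b.requires_grad:
            b._accum(out.grad.sum(axis=(0, 2, 3)))

    out._backward = backward
    return out


def max_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k max pooling (spatial dims must be divisible by k)."""
    N, C, H, W = x.shape
    if H % k or W % k:
        raise ValueError(f"spatial dims {H}x{W} not divisible by pool size {k}")
    Ho, Wo = H // k, W // k
    win = x.data.reshape(N, C, Ho, k, Wo, k).transpose(0, 1, 2, 4, 3, 5)
    flat = win.reshape(N, C, Ho, Wo, k * k)
    idx = np.argmax(flat, axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], -1)[..., 0],
                 x.requires_grad)
    out._prev = (x,)

    def backward() -> None:
        if not x.requires_grad:
            return
        scatter = np.zeros_like(flat)
        np.put_along_axis(scatter, idx[..., None], out.grad[..., None], -1)
        g = scatter.reshape(N, C, Ho, Wo, k, k).transpose(0, 1, 2, 4, 3, 5)
        x._accum(g.reshape(N, C, H, W))

    out._backward = backward
    return out


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """k x k average pooling (spatial dims must be divisible by k)."""
    N, C, H, W = x.shape
    if H % k or W % k:
        raise ValueError(f"spatial dims {H}x{W} not divisible by pool size {k}")
    Ho, Wo = H // k, W // k
    return x.reshape(N, C, Ho, k, Wo, k).mean(axis=(3, 5))


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour spatial upsampling by an integer factor."""
    N, C, H, W = x.shape
    out = Tensor(
        np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3),
        x.requires_grad,
    )
    out._prev = (x,)

    def backward() -> None:
        if x.requires_grad:
            g = out.grad.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5))
            x._accum(g)

    out._backward = backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


def binary_cross_entropy(pred: Tensor, target: np.ndarray,
                         pos_weight: float = 1.0,
                         eps: float = 1e-7) -> Tensor:
    """Weighted-mean BCE between sigmoid outputs and a {0,1} target.

    ``pos_weight`` multiplies the loss of positive pixels; with heavily
    imbalanced masks it keeps the all-negative solution unattractive.
    The weighted sum is normalized by the total weight.
    """
    target = np.asarray(target, dtype=pred.data.dtype)
    p = Tensor(np.clip(pred.data, eps, 1 - eps), pred.requires_grad)
    p._prev = (pred,)

    def backward() -> None:  # pass-through clip gradient
        if pred.requires_grad:
            inside = (pred.data > eps) & (pred.data < 1 - eps)
            pred._accum(p.grad * inside)

    p._backward = backward
    w = 1.0 + (pos_weight - 1.0) * target
    loss = -(Tensor(w * target) * p.log()
             + Tensor(w * (1.0 - target)) * (1.0 - p).log())
    return loss.sum() * (1.0 / w.sum())


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy from raw logits (N, K) and int labels."""
    n = logits.shape[0]
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    log_probs = z - z.exp().sum(axis=1, keepdims=True).log()
    picked = log_probs[np.arange(n), np.asarray(labels)]
    return -picked.mean()
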