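"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This module is the numerical substrate for the trainable model: dense and
convolutional layers, graph filters, batch normalization and the loss are all
composed from the primitives here, and gradients flow back through the tape
built at forward time.  The engine is deliberately small: CPU only, float64
by default, no graph optimization.  Correctness is enforced by central
finite-difference checks in the test suite (`gradcheck`).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv1d",
    "maxpool1d",
    "bce_with_logits",
    "softmax",
    "Adam",
    "gradcheck",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient slot and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = tuple(_parents)

    # ------------------------------------------------------------------ infra

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (must be scalar unless grad given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- arithmetic

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, True, (self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, True, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, True, (self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, True, (self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, True, (self, other))

        def _bw(g):
            a, b = self.data, other.data
            if a.ndim == 2 and b.ndim == 2:
                self._accumulate(g @ b.T)
                other._accumulate(a.T @ g)
            else:  # batched matmul, leading dims broadcast
                self._accumulate(
                    _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
                )
                other._accumulate(
                    _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
                )

        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], True, (self,))

        def _bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = _bw
        return out

    # ------------------------------------------------------------ elementwise

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), True, (self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, True, (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - t**2))
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, True, (self,))
        out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), True, (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, True, (self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / r)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, True, (self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    # ------------------------------------------------------------- reductions

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), True, (self,))

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        val = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out_data = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor(out_data, True, (self,))

        def _bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), gg, axis=axis)
            self._accumulate(full)

        out._backward = _bw
        return out

    # ---------------------------------------------------------------- shaping

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), True, (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), True, (self,))
        inv = np.argsort(axes) if axes else None
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())


# ----------------------------------------------------------------- free ops


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), True, tensors)
    sizes = [t.data.shape[axis] for t in tensors]

    def _bw(g):
        offsets = np.cumsum([0] + sizes)
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Valid 1-D convolution (stride 1, no padding).

    x: (B, W, C_in); weight: (k, C_in, C_out); bias: (C_out,).
    Returns (B, W-k+1, C_out).
    """
    k = weight.data.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(x.data, k, axis=1)
    # win: (B, W-k+1, C_in, k) -> einsum over (k, C_in)
    out_data = np.einsum("bwck,kco->bwo", win, weight.data, optimize=True)
    if bias is not None:
        out_data = out_data + bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, True, parents)

    def _bw(g):
        weight._accumulate(np.einsum("bwck,bwo->kco", win, g, optimize=True))
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 1)))
        dx = np.zeros_like(x.data)
        wout = g.shape[1]
        for kk in range(k):
            # contribution of filter tap kk to input positions kk..kk+wout-1
            dx[:, kk : kk + wout, :] += np.einsum(
                "bwo,co->bwc", g, weight.data[kk], optimize=True
            )
        x._accumulate(dx)

    out._backward = _bw
    return out


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling with floor division of the width.

    x: (B, W, C) -> (B, W//pool, C).  Trailing positions beyond
    pool*(W//pool) are discarded, matching floor(w/p) width arithmetic.
    """
    b, w, c = x.data.shape
    wo = w // pool
    if wo < 1:
        raise ValueError(f"input width {w} shorter than pool size {pool}")
    blocks = x.data[:, : wo * pool, :].reshape(b, wo, pool, c)
    idx = np.argmax(blocks, axis=2)
    out = Tensor(np.max(blocks, axis=2), True, (x,))

    def _bw(g):
        full = np.zeros((b, wo, pool, c))
        np.put_along_axis(full, idx[:, :, None, :], g[:, :, None, :], axis=2)
        dx = np.zeros_like(x.data)
        dx[:, : wo * pool, :] = full.reshape(b, wo * pool, c)
        x._accumulate(dx)

    out._backward = _bw
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float64).reshape(z.shape)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), True, (logits,))

    def _bw(g):
        s = 1.0 / (1.0 + np.exp(-z))
        logits._accumulate(g * (s - y) / z.size)

    out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax composed from primitives."""
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))  # constant shift
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer with the standard bias-corrected moments."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def gradcheck(fn, inputs: list[Tensor], eps: float = 1e-6, atol: float = 1e-5) -> bool:
    """Compare analytic gradients of scalar fn(*inputs) to central differences."""
    out = fn(*inputs)
    for t in inputs:
        t.zero_grad()
    out = fn(*inputs)
    out.backward()
    ok = True
    for t in inputs:
        num = np.zeros_like(t.data)
        flat = t.data.ravel()
        for j in range(flat.size):
            orig = flat[j]
            flat[j] = orig + eps
            lo_hi = fn(*inputs).data.item()
            flat[j] = orig - eps
            lo_lo = fn(*inputs).data.item()
            flat[j] = orig
            num.ravel()[j] = (lo_hi - lo_lo) / (2 * eps)
        if t.grad is None:
            ok = ok and np.allclose(num, 0, atol=atol)
        else:
            ok = ok and np.allclose(num, t.grad, atol=atol)
    return ok
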