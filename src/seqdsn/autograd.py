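"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides the differentiation machinery behind the
domain-separation network: a :class:`Tensor` wrapping an ``ndarray``
together with a dynamically built computation graph, plus the small set
of differentiable operations the model needs (dense algebra, pointwise
nonlinearities, a fused 1-D convolution and a fused LSTM with
hand-written backpropagation-through-time, log-softmax, and a gradient
reversal hook for the adversarial similarity-loss variant).

It is deliberately small: float64 only, CPU only, no graph reuse.
Gradients accumulate into ``Tensor.grad`` after calling
:meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "concat", "grad_reverse", "no_grad"]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


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
    return grad.reshape(shape)


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    # -- graph plumbing ------------------------------------------------

    @classmethod
    def _make(cls, data, parents, backward):
        out = cls(data)
        if _GRAD_ENABLED[0] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        # backward closures never mutate their outputs in place, so
        # storing the array directly (no copy) is safe
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        else:
            grad = _as_array(grad)
        topo: list[Tensor] = []
        seen = set()
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
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def backward(g):
            a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._make(out_data, (a,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(a.data[idx], (a,), backward)

    # -- shape ops -----------------------------------------------------

    def reshape(self, *shape):
        a = self
        orig = a.data.shape

        def backward(g):
            a._accum(g.reshape(orig))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        axes = axes or tuple(reversed(range(a.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), backward)

    @property
    def T(self):
        return self.transpose()

    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            a._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = expit(a.data)

        def backward(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        return self ** 0.5

    def log_softmax(self, axis: int = -1):
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        logsumexp = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - logsumexp
        softmax = np.exp(out_data)

        def backward(g):
            a._accum(g - softmax * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (a,), backward)

    # -- fused sequence layers ----------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor", padding: int):
        """1-D cross-correlation.

        ``self``: (B, C_in, L); ``weight``: (C_out, C_in, K); symmetric
        zero padding of ``padding`` on each side; output (B, C_out, L').
        """
        a, w, b = self, weight, bias
        B, Cin, L = a.data.shape
        Cout, _, K = w.data.shape
        xp = np.pad(a.data, ((0, 0), (0, 0), (padding, padding)))
        Lout = L + 2 * padding - K + 1
        # (B, Cin, K, Lout) view via strides
        s = xp.strides
        windows = np.lib.stride_tricks.as_strided(
            xp, shape=(B, Cin, K, Lout), strides=(s[0], s[1], s[2], s[2]),
            writeable=False)
        out_data = np.einsum("bikl,oik->bol", windows, w.data, optimize=True)
        out_data += b.data[None, :, None]

        def backward(g):
            if w.requires_grad:
                w._accum(np.einsum("bol,bikl->oik", g, windows, optimize=True))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2)))
            if a.requires_grad:
                dxp = np.zeros_like(xp)
                for k in range(K):
                    # dxp[:, ci, k:k+Lout] += sum_o g[:, o, :] * w[o, ci, k]
                    dxp[:, :, k:k + Lout] += np.einsum(
                        "bol,oi->bil", g, w.data[:, :, k], optimize=True)
                da = dxp[:, :, padding:padding + L] if padding else dxp
                a._accum(da)

        return Tensor._make(out_data, (a, w, b), backward)

    def lstm(self, wx: "Tensor", wh: "Tensor", bias: "Tensor"):
        """Single-layer LSTM; returns the final hidden state.

        ``self``: (B, T, I); ``wx``: (I, 4H); ``wh``: (H, 4H);
        ``bias``: (4H,). Gate order i, f, g, o. Hand-written BPTT.
        """
        a = self
        B, T, _ = a.data.shape
        H = wh.data.shape[0]
        x_all = a.data @ wx.data  # (B, T, 4H)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        for t in range(T):
            gates = x_all[:, t, :] + h @ wh.data + bias.data
            i = expit(gates[:, :H])
            f = expit(gates[:, H:2 * H])
            g_ = np.tanh(gates[:, 2 * H:3 * H])
            o = expit(gates[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g_
            tc = np.tanh(c)
            h = o * tc
            cache.append((i, f, g_, o, c_prev, h_prev, tc))

        def backward(grad_h):
            dwx = np.zeros_like(wx.data)
            dwh = np.zeros_like(wh.data)
            db = np.zeros_like(bias.data)
            dx = np.zeros_like(a.data) if a.requires_grad else None
            dh = grad_h.copy()
            dc = np.zeros((B, H))
            for t in range(T - 1, -1, -1):
                i, f, g_, o, c_prev, h_prev, tc = cache[t]
                do = dh * tc
                dc = dc + dh * o * (1.0 - tc ** 2)
                di = dc * g_
                dg = dc * i
                df = dc * c_prev
                da = np.concatenate([
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g_ ** 2),
                    do * o * (1.0 - o),
                ], axis=1)
                dwh += h_prev.T @ da
                db += da.sum(axis=0)
                if dx is not None:
                    dx[:, t, :] = da @ wx.data.T
                dwx += a.data[:, t, :].T @ da
                dh = da @ wh.data.T
                dc = dc * f
            if wx.requires_grad:
                wx._accum(dwx)
            if wh.requires_grad:
                wh._accum(dwh)
            if bias.requires_grad:
                bias._accum(db)
            if dx is not None:
                a._accum(dx)

        return Tensor._make(h, (a, wx, wh, bias), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def grad_reverse(x: Tensor, scale: float = 1.0) -> Tensor:
    """Identity forward; multiplies the incoming gradient by ``-scale``.

    The adversarial (DANN) similarity loss routes the domain
    classifier's gradient through this hook so the shared encoder is
    trained to *confuse* the domain classifier.
    """

    def backward(g):
        x._accum(-scale * g)

    return Tensor._make(x.data.copy(), (x,), backward)
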