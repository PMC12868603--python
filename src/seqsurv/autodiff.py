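"""Minimal reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps an
``ndarray``, records the operations applied to it, and ``backward()``
walks the tape in reverse topological order accumulating gradients.
It supports exactly the operations the sequence-survival model needs —
broadcast arithmetic, (batched) matmul, tanh / sigmoid / softplus / exp /
log, axis reductions, reshape / transpose / concatenate / slicing,
embedding gather, and a masked softmax — nothing more.

All arrays are float64; determinism follows from numpy's.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concatenate", "embedding_lookup", "no_grad"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling tape recording (inference paths)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_own_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED[0]
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if _GRAD_ENABLED[0] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return Tensor._from_op(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out = self.data @ other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._from_op(out, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def tanh(self):
        t = np.tanh(self.data)

        def backward(g, a=self, t=t):
            if a.requires_grad:
                a._accum(g * (1.0 - t**2))

        return Tensor._from_op(t, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g, a=self, s=s):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor._from_op(s, (self,), backward)

    def softplus(self):
        # numerically stable log(1 + e^x)
        x = self.data
        sp = np.where(x > 30, x, np.log1p(np.exp(np.minimum(x, 30))))

        def backward(g, a=self):
            if a.requires_grad:
                sig = 1.0 / (1.0 + np.exp(-np.clip(a.data, -500, 500)))
                a._accum(g * sig)

        return Tensor._from_op(sp, (self,), backward)

    def relu(self):
        out = np.maximum(self.data, 0.0)

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * (a.data > 0))

        return Tensor._from_op(out, (self,), backward)

    def exp(self):
        e = np.exp(np.clip(self.data, -700, 700))

        def backward(g, a=self, e=e):
            if a.requires_grad:
                a._accum(g * e)

        return Tensor._from_op(e, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self):
            if not a.requires_grad:
                return
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._from_op(out, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a1: int, a2: int):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(np.swapaxes(g, a1, a2))

        return Tensor._from_op(np.swapaxes(self.data, a1, a2), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, a=self):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._from_op(self.data[idx], (self,), backward)

    # -- masked softmax over the last axis ------------------------------------
    def masked_softmax(self, mask: np.ndarray):
        """Softmax along the last axis; positions where ``mask`` is False get
        zero probability. ``mask`` broadcasts against the data."""
        x = np.where(mask, self.data, -1e30)
        x = x - x.max(axis=-1, keepdims=True)
        e = np.exp(x)
        s = e / e.sum(axis=-1, keepdims=True)

        def backward(g, a=self, s=s):
            if a.requires_grad:
                dot = (g * s).sum(axis=-1, keepdims=True)
                a._accum(s * (g - dot))

        return Tensor._from_op(s, (self,), backward)

    # -- autograd driver ------------------------------------------------------
    def _accum(self, g: np.ndarray):
        # first contribution is borrowed (never mutated in place); a second
        # contribution allocates, so shared gradient buffers stay intact
        if self.grad is None:
            self.grad = g
            self._own_grad = False
        elif not self._own_grad:
            self.grad = self.grad + g
            self._own_grad = True
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tensors, offsets=offsets):
        sl = [slice(None)] * g.ndim
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._from_op(out, tuple(tensors), backward)


def embedding_lookup(table: Tensor, ids: np.ndarray) -> Tensor:
    """Gather rows ``table[ids]`` with scatter-add gradient into the table."""
    ids = np.asarray(ids)

    def backward(g, t=table, ids=ids):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            np.add.at(full, ids.reshape(-1), g.reshape(-1, t.data.shape[-1]))
            t._accum(full)

    return Tensor._from_op(table.data[ids], (table,), backward)


class Adam:
    """Adam with bias correction; state keyed by parameter identity."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
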