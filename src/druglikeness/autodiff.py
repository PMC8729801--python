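"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the GRU language model and the gated
graph-attention classifier need: broadcasting arithmetic, (batched) matrix
products, the usual pointwise nonlinearities, masked softmax, fused
cross-entropy losses, row gathering for embeddings, concatenation and
column slicing.  Gradients are accumulated by topologically-sorted
backward passes; correctness is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_rows",
    "softmax_cross_entropy",
    "bce_with_logits",
    "masked_softmax",
    "Adam",
    "clip_global_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs from long sequences recurse deep
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = self.data @ other.data

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor(out, parents=(self, other), backward=bwd)

    # ------------------------------------------------------- nonlinearities
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g, a=self, s=s):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return Tensor(s, parents=(self,), backward=bwd)

    def tanh(self):
        t = np.tanh(self.data)

        def bwd(g, a=self, t=t):
            if a.requires_grad:
                a._accum(g * (1.0 - t * t))

        return Tensor(t, parents=(self,), backward=bwd)

    def relu(self):
        m = self.data > 0

        def bwd(g, a=self, m=m):
            if a.requires_grad:
                a._accum(g * m)

        return Tensor(self.data * m, parents=(self,), backward=bwd)

    # ------------------------------------------------------------ shaping
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor(out, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def slice_cols(self, start: int, stop: int):
        """Slice the last axis; gradient scatters back into place."""
        out = self.data[..., start:stop]

        def bwd(g, a=self, start=start, stop=stop):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[..., start:stop] = g
                a._accum(full)

        return Tensor(out, parents=(self,), backward=bwd)

    def transpose_last2(self):
        out = np.swapaxes(self.data, -1, -2)

        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(np.swapaxes(g, -1, -2))

        return Tensor(out, parents=(self,), backward=bwd)


# ---------------------------------------------------------------- functions

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g, ts=tuple(tensors), offsets=offsets, axis=axis):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    return Tensor(out, parents=tuple(tensors), backward=bwd)


def gather_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """table[idx] with gradient scatter-add (embedding lookup)."""
    idx = np.asarray(idx)
    out = table.data[idx]

    def bwd(g, t=table, idx=idx):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            np.add.at(full, idx.reshape(-1), g.reshape(-1, t.data.shape[-1]))
            t._accum(full)

    return Tensor(out, parents=(table,), backward=bwd)


def _log_softmax(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=-1, keepdims=True)
    z = x - m
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray,
                          mask: np.ndarray | None = None) -> Tensor:
    """Summed cross-entropy of integer `targets` under `logits` rows.

    `logits` is (..., V); `targets` integer array of the leading shape;
    `mask` (same leading shape) zeroes out padded positions.
    """
    targets = np.asarray(targets)
    lsm = _log_softmax(logits.data)
    picked = np.take_along_axis(lsm, targets[..., None], axis=-1)[..., 0]
    if mask is None:
        mask = np.ones(targets.shape)
    loss = -(picked * mask).sum()

    def bwd(g, lg=logits, lsm=lsm, targets=targets, mask=mask):
        if not lg.requires_grad:
            return
        p = np.exp(lsm)
        grad = p.copy()
        np.put_along_axis(
            grad, targets[..., None],
            np.take_along_axis(grad, targets[..., None], axis=-1) - 1.0, axis=-1)
        lg._accum(g * grad * mask[..., None])

    return Tensor(loss, parents=(logits,), backward=bwd)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Summed binary cross-entropy, numerically fused with the sigmoid."""
    x = logits.data
    t = np.asarray(targets, dtype=np.float64)
    # log(1+e^x) computed stably
    loss = (np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))).sum()

    def bwd(g, lg=logits, x=x, t=t):
        if lg.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
            lg._accum(g * (s - t))

    return Tensor(loss, parents=(logits,), backward=bwd)


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to mask==1 entries.

    Rows whose mask is entirely zero produce all-zero outputs.
    """
    mask = np.asarray(mask, dtype=bool)
    neg = np.where(mask, scores.data, -np.inf)
    m = neg.max(axis=-1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.exp(neg - m) * mask
    denom = e.sum(axis=-1, keepdims=True)
    safe = np.where(denom > 0, denom, 1.0)
    p = e / safe

    def bwd(g, sc=scores, p=p):
        if sc.requires_grad:
            dot = (g * p).sum(axis=-1, keepdims=True)
            sc._accum(p * (g - dot))

    return Tensor(p, parents=(scores,), backward=bwd)


# ---------------------------------------------------------------- training

def clip_global_norm(params: dict[str, Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most `max_norm`."""
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = total ** 0.5
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale
    return norm


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
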