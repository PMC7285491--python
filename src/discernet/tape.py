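"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough of a tape for training the hierarchical GRU models in this
package: 2-D/3-D matmul, broadcast add/mul, the saturating nonlinearities,
sequence stacking/gathering, masked softmax attention and a fused weighted
softmax cross-entropy. Gradients are checked against central finite
differences in the test suite.

Design notes: values are plain ``np.ndarray``; a :class:`Tensor` wraps a
value, its accumulated gradient and a backward closure. Only tensors with
``requires_grad`` (parameters and anything downstream of them) participate in
the backward sweep — frozen embeddings enter as constants and cost nothing.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


class Tensor:
    __slots__ = ("value", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(
        self,
        value: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
        requires_grad: bool = False,
    ):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = parents
        self.backward_fn = backward_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.value.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.value)
        self.grad += g

    def backward(self) -> None:
        """Reverse-topological sweep seeding d(self)/d(self) = 1."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)


def constant(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64))


def parameter(x: np.ndarray) -> Tensor:
    """Wrap an array as a trainable leaf. The array is NOT copied, so an
    optimizer may update it in place between tapes."""
    t = Tensor(np.asarray(x, dtype=np.float64))
    t.requires_grad = True
    return t


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast to reach g.shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value + b.value, (a, b))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.value.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.value.shape))

    out.backward_fn = bwd
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.value * b.value, (a, b))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.value, a.value.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.value, b.value.shape))

    out.backward_fn = bwd
    return out


def scale_add(a: Tensor, scale: float = 1.0, shift: float = 0.0) -> Tensor:
    """scale * a + shift with python scalars (e.g. 1 - z as scale=-1, shift=1)."""
    out = Tensor(scale * a.value + shift, (a,))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(scale * g)

    out.backward_fn = bwd
    return out


def matmul(a: Tensor, w: Tensor) -> Tensor:
    """a @ w where a is (..., D_in) stacked in ≤3 dims and w is (D_in, D_out)."""
    out = Tensor(a.value @ w.value, (a, w))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g @ w.value.T)
        if w.requires_grad:
            av, gv = a.value, g
            if av.ndim == 3:
                av = av.reshape(-1, av.shape[-1])
                gv = gv.reshape(-1, gv.shape[-1])
            w.accumulate(av.T @ gv)

    out.backward_fn = bwd
    return out


def matmul_t(a: Tensor, w: Tensor) -> Tensor:
    """a @ w.T for weights stored row-major as (D_out, D_in); a is (..., D_in)."""
    out = Tensor(a.value @ w.value.T, (a, w))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g @ w.value)
        if w.requires_grad:
            g2 = g.reshape(-1, g.shape[-1])
            a2 = a.value.reshape(-1, a.value.shape[-1])
            w.accumulate(g2.T @ a2)

    out.backward_fn = bwd
    return out


def select_step(x: Tensor, t: int) -> Tensor:
    """x[:, t, :] with scatter-back gradient."""
    out = Tensor(x.value[:, t, :], (x,))

    def bwd(g):
        if x.requires_grad:
            acc = np.zeros_like(x.value)
            acc[:, t, :] = g
            x.accumulate(acc)

    out.backward_fn = bwd
    return out


def sigmoid(a: Tensor) -> Tensor:
    val = 1.0 / (1.0 + np.exp(-a.value))
    out = Tensor(val, (a,))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g * val * (1.0 - val))

    out.backward_fn = bwd
    return out


def tanh(a: Tensor) -> Tensor:
    val = np.tanh(a.value)
    out = Tensor(val, (a,))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g * (1.0 - val * val))

    out.backward_fn = bwd
    return out


def relu(a: Tensor) -> Tensor:
    val = np.maximum(a.value, 0.0)
    out = Tensor(val, (a,))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g * (a.value > 0))

    out.backward_fn = bwd
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.value.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t.accumulate(piece)

    out.backward_fn = bwd
    return out


def stack(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.stack([t.value for t in tensors], axis=axis), tuple(tensors))

    def bwd(g):
        pieces = np.moveaxis(g, axis, 0)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t.accumulate(piece)

    out.backward_fn = bwd
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Rows of x selected by a (possibly multi-dim) integer index; index -1
    yields a zero row (used for padding slots). Gradient scatters back."""
    idx = np.asarray(index)
    padded = np.vstack([x.value, np.zeros((1, x.value.shape[1]))])
    safe = np.where(idx < 0, x.value.shape[0], idx)
    out = Tensor(padded[safe], (x,))

    def bwd(g):
        if x.requires_grad:
            acc = np.zeros_like(x.value)
            flat_idx = idx.reshape(-1)
            flat_g = g.reshape(-1, g.shape[-1])
            keep = flat_idx >= 0
            np.add.at(acc, flat_idx[keep], flat_g[keep])
            x.accumulate(acc)

    out.backward_fn = bwd
    return out


def dot_last(x: Tensor, q: Tensor, scale: float = 1.0) -> Tensor:
    """scale * <x[..., :], q> over the last axis: (B, T, D) x (D,) -> (B, T)."""
    out = Tensor(scale * (x.value @ q.value), (x, q))

    def bwd(g):
        if x.requires_grad:
            x.accumulate(scale * g[..., None] * q.value)
        if q.requires_grad:
            d = x.value.shape[-1]
            q.accumulate(scale * (g.reshape(-1) @ x.value.reshape(-1, d)))

    out.backward_fn = bwd
    return out


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax over the last axis with masked positions forced to 0
    weight; computed with max-subtraction. mask is 1 for real positions."""
    m = np.asarray(mask, dtype=bool)
    s = np.where(m, scores.value, -np.inf)
    s_max = np.max(s, axis=-1, keepdims=True)
    e = np.exp(s - s_max)
    alpha = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(alpha, (scores,))

    def bwd(g):
        if scores.requires_grad:
            inner = (g * alpha).sum(axis=-1, keepdims=True)
            scores.accumulate(alpha * (g - inner) * m)

    out.backward_fn = bwd
    return out


def weighted_sum(alpha: Tensor, o: Tensor) -> Tensor:
    """z_b = sum_t alpha[b,t] * o[b,t,:]."""
    out = Tensor(np.einsum("bt,btd->bd", alpha.value, o.value), (alpha, o))

    def bwd(g):
        if alpha.requires_grad:
            alpha.accumulate(np.einsum("bd,btd->bt", g, o.value))
        if o.requires_grad:
            o.accumulate(alpha.value[:, :, None] * g[:, None, :])

    out.backward_fn = bwd
    return out


def dropout(a: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: zero with probability p, survivors scaled by 1/(1-p)."""
    if p <= 0.0:
        return a
    keep = (rng.random(a.value.shape) >= p) / (1.0 - p)
    return mul(a, constant(keep))


def softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, weights: np.ndarray
) -> tuple[Tensor, np.ndarray]:
    """Mean of per-example weighted CE over the batch; also returns the
    softmax probabilities (as a plain array) for metric computation."""
    z = logits.value - logits.value.max(axis=-1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=-1, keepdims=True)
    n = logits.value.shape[0]
    y = np.asarray(labels, dtype=int)
    w = np.asarray(weights, dtype=float)
    logp = z - np.log(e.sum(axis=-1, keepdims=True))
    losses = -w * logp[np.arange(n), y]
    out = Tensor(np.array(losses.mean()), (logits,))

    def bwd(g):
        if logits.requires_grad:
            onehot = np.zeros_like(probs)
            onehot[np.arange(n), y] = 1.0
            logits.accumulate(g * (probs - onehot) * w[:, None] / n)

    out.backward_fn = bwd
    return out, probs
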