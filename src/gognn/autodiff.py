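"""Minimal reverse-mode automatic differentiation over numpy arrays.

The dual graph convolutional model is small (a handful of dense matrices per
convolution step plus an MLP head), so a compact tape-based autodiff with
exactly the operations the model needs — dense products, degree-bucketed
linear maps, gather/segment-sum for graph aggregation, ReLU, row-wise softmax,
dropout and a fused softmax cross-entropy — is sufficient and keeps the whole
computation in float64, which the finite-difference gradient tests rely on.

Gradients are accumulated by a topological backward sweep from the scalar
loss, micrograd-style.  All arrays are ``float64``; integer index arrays are
kept outside the tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "matmul",
    "bucket_linear",
    "gather_rows",
    "segment_sum",
    "relu",
    "softmax_rows",
    "concat_cols",
    "add_bias",
    "dropout",
    "cross_entropy_with_logits",
]


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None, name=""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this scalar through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep for large T*L
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic sugar (only what the model uses) --------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor(a.data + b.data, _parents=(a, b), _backward=bwd)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor(a.data * b.data, _parents=(a, b), _backward=bwd)

    __radd__ = __add__
    __rmul__ = __mul__

    def sum(self):
        a = self

        def bwd(g):
            if a.requires_grad:
                a._accumulate(np.full_like(a.data, float(g)))

        return Tensor(a.data.sum(), _parents=(a,), _backward=bwd)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor(a.data @ b.data, _parents=(a, b), _backward=bwd)


def bucket_linear(x: Tensor, weights: Tensor, buckets: np.ndarray) -> Tensor:
    """Row-wise linear map with a per-row weight matrix chosen by bucket.

    ``out[n] = weights[buckets[n]] @ x[n]`` where ``weights`` is a stack of
    shape ``(n_buckets, d, d)``.  This is how degree-specific convolution
    weights are applied to all atoms of a batch at once.
    """
    buckets = np.asarray(buckets, dtype=np.intp)
    out = np.einsum("nd,nod->no", x.data, weights.data[buckets])

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.einsum("no,nod->nd", g, weights.data[buckets]))
        if weights.requires_grad:
            gw = np.zeros_like(weights.data)
            for b in np.unique(buckets):
                rows = buckets == b
                gw[b] = g[rows].T @ x.data[rows]
            weights._accumulate(gw)

    return Tensor(out, _parents=(x, weights), _backward=bwd)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, idx, g)
            x._accumulate(gx)

    return Tensor(x.data[idx], _parents=(x,), _backward=bwd)


def segment_sum(x: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` groups given by ``segments``."""
    segments = np.asarray(segments, dtype=np.intp)
    out = np.zeros((n_segments, x.data.shape[1]), dtype=np.float64)
    np.add.at(out, segments, x.data)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g[segments])

    return Tensor(out, _parents=(x,), _backward=bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(x.data * mask, _parents=(x,), _backward=bwd)


def softmax_rows(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(p * (g - (g * p).sum(axis=-1, keepdims=True)))

    return Tensor(p, _parents=(x,), _backward=bwd)


def concat_cols(a: Tensor, b: Tensor) -> Tensor:
    na = a.data.shape[1]

    def bwd(g):
        if a.requires_grad:
            a._accumulate(g[:, :na])
        if b.requires_grad:
            b._accumulate(g[:, na:])

    return Tensor(np.concatenate([a.data, b.data], axis=1), _parents=(a, b), _backward=bwd)


def add_bias(x: Tensor, bias: Tensor) -> Tensor:
    def bwd(g):
        if x.requires_grad:
            x._accumulate(g)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=0))

    return Tensor(x.data + bias.data, _parents=(x, bias), _backward=bwd)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; call only in train mode (identity when rate==0)."""
    if rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * keep)

    return Tensor(x.data * keep, _parents=(x,), _backward=bwd)


def cross_entropy_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Summed softmax cross-entropy, fused for numerical stability.

    Returns the *sum* over samples of ``-log p_{t_i}`` (the training loss is a
    batch sum, not a mean).
    """
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    loss = -logp[np.arange(len(labels)), labels].sum()

    def bwd(g):
        if logits.requires_grad:
            grad = np.exp(logp)
            grad[np.arange(len(labels)), labels] -= 1.0
            logits._accumulate(float(g) * grad)

    return Tensor(loss, _parents=(logits,), _backward=bwd)
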