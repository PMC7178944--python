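"""External (inter-compound network) graph convolution.

Compound vectors from the internal convolution are refined for ``L`` steps by

    g_i^(l+1) = f( U[l] g_i^(l) + sum_{m in A_i} V[l] g_m^(l) )

with one (U, V) pair per step and no degree conditioning (external degrees
are large and varied).  The final representation pools every step:

    h_i = softmax( sum_{l=0..L} g_i^(l) )

Both the intermediate activation f and the pooling nonlinearity default to
row-wise softmax.  The adjacency used for message passing should normally
contain training-positive edges only, so that no test link leaks into the
representation.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, gather_rows, matmul, segment_sum
from .gog import GoG, edge_arrays
from .internal import ACTIVATIONS


class ExternalConvParams:
    """Per-step weight matrices U (self) and V (neighbors)."""

    def __init__(
        self,
        dim: int,
        n_steps: int,
        f_activation: str = "softmax",
        sigma_activation: str = "softmax",
        seed: int = 0,
        init_scale: float = 0.1,
    ):
        # init is an order of magnitude below the internal convolution's:
        # external pre-activations sum over node degrees that can reach
        # hundreds, and a large initial V saturates the softmax, erasing
        # degree gradations before training can exploit them
        for a in (f_activation, sigma_activation):
            if a not in ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")
        self.dim = dim
        self.n_steps = n_steps
        self.f_activation = f_activation
        self.sigma_activation = sigma_activation
        rng = np.random.default_rng(seed)
        self.U = [
            Tensor(rng.normal(0, init_scale, (dim, dim)), requires_grad=True, name=f"U{l}")
            for l in range(n_steps)
        ]
        self.V = [
            Tensor(rng.normal(0, init_scale, (dim, dim)), requires_grad=True, name=f"V{l}")
            for l in range(n_steps)
        ]

    def tensors(self) -> list[Tensor]:
        return [*self.U, *self.V]


def external_convolve(
    g_vectors,
    params: ExternalConvParams,
    message_adjacency: list[list[int]],
) -> Tensor:
    """Refined per-compound representations h, shape (n_compounds, d).

    ``message_adjacency`` is the symmetric neighbor-list the convolution may
    see (normally training positives only); isolated compounds use only the
    self term.
    """
    states = g_vectors if isinstance(g_vectors, Tensor) else Tensor(g_vectors)
    n = states.shape[0]
    if len(message_adjacency) != n:
        raise ValueError("message adjacency length != compound count")
    src, dst = edge_arrays(message_adjacency)
    if len(src) and (src.max() >= n or dst.max() >= n):
        raise ValueError("adjacency index out of range")
    if states.shape[1] != params.dim:
        raise ValueError("dimension mismatch")
    f = ACTIVATIONS[params.f_activation]
    sigma = ACTIVATIONS[params.sigma_activation]
    total = states
    for l in range(params.n_steps):
        pre = matmul(states, _transpose(params.U[l]))
        if len(src):
            agg = segment_sum(gather_rows(states, src), dst, n)
            pre = pre + matmul(agg, _transpose(params.V[l]))
        states = f(pre)
        total = total + states
    return sigma(total)


def _transpose(w: Tensor) -> Tensor:
    # states are stored row-wise, so g W^T computes W g per compound
    def bwd(g):
        if w.requires_grad:
            w._accumulate(g.T)

    return Tensor(w.data.T, _parents=(w,), _backward=bwd)


def gog_message_adjacency(gog: GoG, edges: list[tuple[int, int]] | None) -> list[list[int]]:
    """Build a symmetric neighbor list from an explicit edge subset.

    ``edges=None`` uses the GoG's full external adjacency (only appropriate
    when no held-out links exist).
    """
    if edges is None:
        return gog.external_adjacency
    adj: list[list[int]] = [[] for _ in range(gog.n_compounds)]
    for i, j in {(min(a, b), max(a, b)) for a, b in edges}:
        adj[i].append(j)
        adj[j].append(i)
    return adj
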