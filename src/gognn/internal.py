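"""Internal (molecular) graph convolution.

Each atom starts from a trainable embedding keyed by its signature and is
updated for ``T`` steps by

    v_k^(t+1) = f( W[t, deg(k)] v_k^(t) + sum_{m in A_k} M[t, deg(k)] v_m^(t) )

with degree-specific weight matrices (neural-fingerprint style; bond types
are ignored).  The compound vector pools every step including the raw
embedding:

    g = sum_k softmax( sum_{t=0..T} v_k^(t) )

so the components of ``g`` sum to the number of atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import (
    Tensor,
    bucket_linear,
    gather_rows,
    relu,
    segment_sum,
    softmax_rows,
)
from .gog import AtomSignature, InternalGraph, edge_arrays

logger = logging.getLogger(__name__)

ACTIVATIONS = {
    "relu": relu,
    "identity": lambda x: x,
    "softmax": softmax_rows,
}

#: degrees above this share the top weight bucket (organic valence cap);
#: degree 0 keeps its own bucket, so there are D_MAX+1 buckets in total.
D_MAX = 5


def degree_bucket(degree: int, d_max: int = D_MAX) -> int:
    return 0 if degree == 0 else min(degree, d_max)


class AtomEmbeddingTable:
    """Trainable Gaussian-initialized embeddings, one row per atom signature.

    Rows are drawn N(0, init_scale^2) per component, one draw per distinct
    signature.  A dedicated fallback row (same initialization) handles
    signatures unseen at table-construction time; its first use is logged.
    """

    def __init__(
        self,
        signatures: list[AtomSignature],
        dim: int,
        seed: int = 0,
        init_scale: float = 0.1,
    ):
        self.dim = dim
        self.rng_seed = seed
        uniq = sorted(set(signatures), key=lambda s: s.key())
        self.index = {sig: i for i, sig in enumerate(uniq)}
        rng = np.random.default_rng(seed)
        # last row = fallback for unseen signatures
        self.weights = Tensor(
            rng.normal(0.0, init_scale, size=(len(uniq) + 1, dim)),
            requires_grad=True,
            name="atom_table",
        )
        self._warned_unseen = False

    @property
    def fallback_row(self) -> int:
        return self.weights.shape[0] - 1

    def rows_for(self, signatures: list[AtomSignature]) -> np.ndarray:
        rows = np.empty(len(signatures), dtype=np.intp)
        for i, sig in enumerate(signatures):
            r = self.index.get(sig)
            if r is None:
                if not self._warned_unseen:
                    logger.warning(
                        "unseen atom signature %s: using fallback embedding", sig
                    )
                    self._warned_unseen = True
                r = self.fallback_row
            rows[i] = r
        return rows

    def signatures(self) -> list[AtomSignature]:
        return sorted(self.index, key=lambda s: s.key())


class InternalConvParams:
    """Per-step, per-degree-bucket weight matrices W (self) and M (neighbors)."""

    def __init__(
        self,
        dim: int,
        n_steps: int,
        d_max: int = D_MAX,
        activation: str = "relu",
        seed: int = 0,
        init_scale: float = 1.0,
    ):
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.dim = dim
        self.n_steps = n_steps
        self.d_max = d_max
        self.activation = activation
        n_buckets = d_max + 1
        rng = np.random.default_rng(seed)
        self.W = [
            Tensor(rng.normal(0, init_scale, (n_buckets, dim, dim)), requires_grad=True, name=f"W{t}")
            for t in range(n_steps)
        ]
        self.M = [
            Tensor(rng.normal(0, init_scale, (n_buckets, dim, dim)), requires_grad=True, name=f"M{t}")
            for t in range(n_steps)
        ]

    def tensors(self) -> list[Tensor]:
        return [*self.W, *self.M]


@dataclass
class PackedAtoms:
    """All atoms of a compound set flattened for batched convolution."""

    sig_rows: np.ndarray      # embedding-table row per atom
    buckets: np.ndarray       # degree bucket per atom
    src: np.ndarray           # bond endpoints (both directions), global indices
    dst: np.ndarray
    compound_of: np.ndarray   # compound index per atom
    n_compounds: int

    @property
    def n_atoms(self) -> int:
        return len(self.sig_rows)


def pack_graphs(
    graphs: list[InternalGraph], table: AtomEmbeddingTable, d_max: int = D_MAX
) -> PackedAtoms:
    sig_rows, buckets, compound_of = [], [], []
    src_all, dst_all = [], []
    offset = 0
    for ci, g in enumerate(graphs):
        sig_rows.append(table.rows_for(g.atoms))
        buckets.extend(degree_bucket(len(nbrs), d_max) for nbrs in g.adjacency)
        compound_of.extend([ci] * g.n_atoms)
        src, dst = edge_arrays(g.adjacency)
        src_all.append(src + offset)
        dst_all.append(dst + offset)
        offset += g.n_atoms
    return PackedAtoms(
        sig_rows=np.concatenate(sig_rows) if sig_rows else np.empty(0, dtype=np.intp),
        buckets=np.asarray(buckets, dtype=np.intp),
        src=np.concatenate(src_all) if src_all else np.empty(0, dtype=np.intp),
        dst=np.concatenate(dst_all) if dst_all else np.empty(0, dtype=np.intp),
        compound_of=np.asarray(compound_of, dtype=np.intp),
        n_compounds=len(graphs),
    )


def _step(states, src, dst, buckets, params, t):
    act = ACTIVATIONS[params.activation]
    pre = bucket_linear(states, params.W[t], buckets)
    if len(src):
        agg = segment_sum(gather_rows(states, src), dst, states.shape[0])
        pre = pre + bucket_linear(agg, params.M[t], buckets)
    return act(pre)


def internal_step(
    states, graph: InternalGraph, params: InternalConvParams, t: int
) -> Tensor:
    """One convolution update on a single molecule's per-atom states."""
    states = states if isinstance(states, Tensor) else Tensor(states)
    if states.shape[0] != graph.n_atoms:
        raise ValueError("states length != atom count")
    if not 0 <= t < params.n_steps:
        raise ValueError(f"step {t} outside [0, {params.n_steps})")
    if states.shape[1] != params.dim:
        raise ValueError("state dimension mismatch")
    src, dst = edge_arrays(graph.adjacency)
    buckets = np.asarray(
        [degree_bucket(len(nbrs), params.d_max) for nbrs in graph.adjacency], dtype=np.intp
    )
    return _step(states, src, dst, buckets, params, t)


def internal_convolve_packed(
    packed: PackedAtoms, table: AtomEmbeddingTable, params: InternalConvParams
) -> Tensor:
    """Compound vectors for a packed compound set, shape (n_compounds, d)."""
    if packed.n_atoms == 0:
        raise ValueError("empty compound set")
    states = gather_rows(table.weights, packed.sig_rows)
    total = states
    for t in range(params.n_steps):
        states = _step(states, packed.src, packed.dst, packed.buckets, params, t)
        total = total + states
    per_atom = softmax_rows(total)
    return segment_sum(per_atom, packed.compound_of, packed.n_compounds)


def internal_convolve(
    graph: InternalGraph, table: AtomEmbeddingTable, params: InternalConvParams
) -> Tensor:
    """Compound vector g for a single molecule, shape (1, d)."""
    packed = pack_graphs([graph], table, params.d_max)
    return internal_convolve_packed(packed, table, params)
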