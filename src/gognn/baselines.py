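"""Non-neural baselines: classical similarity indices and hashed fingerprints.

Similarity indices score a compound pair from the external network alone:
common neighbors |N(i) ∩ N(j)|, Jaccard |N(i) ∩ N(j)| / |N(i) ∪ N(j)|, and
the Katz index — entry (i, j) of (I - βA)^{-1} - I, i.e. the β-damped count
of paths of every length.  To avoid label leakage they should be computed on
the training-positive adjacency only.

The hashed Morgan fingerprint is the classical circular substructure
descriptor: atom environments are iteratively re-hashed from their neighbors
for ``radius`` rounds and every (atom, round) environment identifier is
folded into a fixed-width bit vector.  Hashing uses blake2b, so fingerprints
are stable across runs and platforms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .gog import GoG, InternalGraph

SIMILARITY_INDICES = ("common_neighbors", "jaccard", "katz")
DEFAULT_BETA = 0.001


@dataclass
class Fingerprint:
    bits: np.ndarray
    radius: int

    @property
    def nbits(self) -> int:
        return len(self.bits)

    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


class KatzDivergenceError(ValueError):
    """β at or above 1/spectral-radius: the Katz series does not converge."""


def _adjacency_matrix(adjacency: list[list[int]]) -> sp.csr_matrix:
    n = len(adjacency)
    rows = [i for i, nbrs in enumerate(adjacency) for _ in nbrs]
    cols = [j for nbrs in adjacency for j in nbrs]
    return sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))


def _spectral_radius(a: sp.csr_matrix) -> float:
    n = a.shape[0]
    if a.nnz == 0:
        return 0.0
    if n <= 200:
        return float(np.max(np.abs(np.linalg.eigvalsh(a.toarray()))))
    return float(abs(spla.eigsh(a, k=1, which="LM", return_eigenvectors=False)[0]))


def katz_scores(
    adjacency: list[list[int]], pairs, beta: float = DEFAULT_BETA
) -> np.ndarray:
    """Katz index for each queried pair via sparse solves on queried columns."""
    a = _adjacency_matrix(adjacency)
    radius = _spectral_radius(a)
    if radius > 0 and beta >= 1.0 / radius:
        raise KatzDivergenceError(
            f"beta={beta} >= 1/spectral radius ({1.0 / radius:.6g}); Katz series diverges"
        )
    n = a.shape[0]
    system = (sp.identity(n, format="csc") - beta * a.tocsc())
    lu = spla.splu(system)
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    cols = {}
    for j in np.unique(pairs[:, 1]):
        e = np.zeros(n)
        e[j] = 1.0
        cols[int(j)] = lu.solve(e)
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        out[k] = cols[int(j)][i] - (1.0 if i == j else 0.0)
    return out


def similarity_scores(
    adjacency: list[list[int]],
    pairs,
    index: str,
    beta: float = DEFAULT_BETA,
) -> np.ndarray:
    """Score compound pairs by a classical link-prediction index."""
    if index not in SIMILARITY_INDICES:
        raise ValueError(f"unknown index {index!r}; choose from {SIMILARITY_INDICES}")
    if index == "katz":
        return katz_scores(adjacency, pairs, beta)
    nbr = [set(nbrs) for nbrs in adjacency]
    pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        inter = len(nbr[i] & nbr[j])
        if index == "common_neighbors":
            out[k] = inter
        else:
            union = len(nbr[i] | nbr[j])
            out[k] = inter / union if union else 0.0
    return out


# ----------------------------------------------------------------------
def _h64(text: str) -> int:
    return int.from_bytes(hashlib.blake2b(text.encode(), digest_size=8).digest(), "big")


def morgan_fingerprint(
    graph: InternalGraph, radius: int = 2, nbits: int = 2048
) -> Fingerprint:
    """Hashed circular fingerprint by iterative neighborhood re-hashing."""
    graph.validate()
    ids = [_h64(sig.key()) for sig in graph.atoms]
    bits = np.zeros(nbits, dtype=np.float64)
    for h in ids:
        bits[h % nbits] = 1.0
    for _ in range(radius):
        new_ids = []
        for k, nbrs in enumerate(graph.adjacency):
            env = ",".join(str(x) for x in sorted(ids[m] for m in nbrs))
            new_ids.append(_h64(f"{ids[k]}|{env}"))
        ids = new_ids
        for h in ids:
            bits[h % nbits] = 1.0
    return Fingerprint(bits=bits, radius=radius)


def fingerprint_mode_features(
    gog: GoG, radius: int = 2, nbits: int = 2048
) -> np.ndarray:
    """Frozen per-compound fingerprint matrix feeding the link predictor."""
    return np.stack(
        [morgan_fingerprint(c, radius, nbits).bits for c in gog.compounds]
    )
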