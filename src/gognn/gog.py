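"""Data model for graphs of graphs (GoG).

A GoG is a two-level structure: an *external* network whose nodes are chemical
compounds, each compound carrying its own *internal* molecular graph (atoms as
nodes, bonds as edges).  Atoms are identified by a discrete *signature* —
element, valence, hydrogen count, degree and aromaticity — which keys the
trainable initial atom embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

DEFAULT_MAX_ATOMS = 64


class GoGValidationError(ValueError):
    """Base class for structural validation failures."""


class UnknownCompoundError(GoGValidationError):
    pass


class SelfLoopError(GoGValidationError):
    pass


class DuplicateCompoundError(GoGValidationError):
    pass


@dataclass(frozen=True)
class AtomSignature:
    """Discrete atom identity used to key the initial embedding table."""

    element: str
    valence: int
    hydrogen_count: int
    degree: int
    aromatic: bool = False

    def __post_init__(self):
        if self.valence < 0 or self.hydrogen_count < 0 or self.degree < 0:
            raise GoGValidationError(f"negative field in signature {self}")

    def key(self) -> str:
        """Stable serialization used in checkpoints and hashing."""
        return f"{self.element}|{self.valence}|{self.hydrogen_count}|{self.degree}|{int(self.aromatic)}"

    @classmethod
    def from_key(cls, key: str) -> "AtomSignature":
        el, val, h, deg, ar = key.split("|")
        return cls(el, int(val), int(h), int(deg), bool(int(ar)))


@dataclass
class InternalGraph:
    """One compound: labeled atoms plus a symmetric bond adjacency list."""

    graph_id: str
    atoms: list[AtomSignature]
    adjacency: list[list[int]]

    def __post_init__(self):
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def validate(self, max_atoms: int | None = None) -> None:
        n = len(self.atoms)
        if n < 1:
            raise GoGValidationError(f"{self.graph_id}: empty molecule")
        if max_atoms is not None and n > max_atoms:
            raise GoGValidationError(f"{self.graph_id}: {n} atoms exceeds cap {max_atoms}")
        if len(self.adjacency) != n:
            raise GoGValidationError(f"{self.graph_id}: adjacency length != atom count")
        for k, nbrs in enumerate(self.adjacency):
            for m in nbrs:
                if not 0 <= m < n:
                    raise GoGValidationError(f"{self.graph_id}: neighbor {m} out of range")
                if m == k:
                    raise SelfLoopError(f"{self.graph_id}: self-loop at atom {k}")
                if k not in self.adjacency[m]:
                    raise GoGValidationError(f"{self.graph_id}: asymmetric bond {k}-{m}")
            if self.atoms[k].degree != len(nbrs):
                raise GoGValidationError(
                    f"{self.graph_id}: atom {k} signature degree "
                    f"{self.atoms[k].degree} != adjacency degree {len(nbrs)}"
                )

    def edge_list(self) -> list[tuple[int, int]]:
        return [(k, m) for k, nbrs in enumerate(self.adjacency) for m in nbrs if k < m]


@dataclass
class GoG:
    """A set of compounds plus the undirected external network among them."""

    compounds: list[InternalGraph]
    external_adjacency: list[list[int]]
    id_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        ids = [c.graph_id for c in self.compounds]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateCompoundError(f"duplicate compound ids: {dup}")
        self.id_index = {gid: i for i, gid in enumerate(ids)}
        n = len(self.compounds)
        if len(self.external_adjacency) != n:
            raise GoGValidationError("external adjacency length != compound count")
        for i, nbrs in enumerate(self.external_adjacency):
            for j in nbrs:
                if not 0 <= j < n:
                    raise GoGValidationError(f"external neighbor {j} out of range")
                if j == i:
                    raise SelfLoopError(f"external self-loop at compound {i}")
                if i not in self.external_adjacency[j]:
                    raise GoGValidationError(f"asymmetric external edge {i}-{j}")

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    def external_edges(self) -> list[tuple[int, int]]:
        """Unique undirected edges as sorted index pairs."""
        return [
            (i, j)
            for i, nbrs in enumerate(self.external_adjacency)
            for j in nbrs
            if i < j
        ]

    def edge_set(self) -> set[tuple[int, int]]:
        return set(self.external_edges())


@dataclass
class LinkDataset:
    """Labeled compound pairs for training or testing."""

    pairs: list[tuple[int, int, int]]
    role: str = "train"

    def __post_init__(self):
        seen = set()
        for i, j, t in self.pairs:
            if i == j:
                raise GoGValidationError(f"pair ({i},{i}) is a self-pair")
            if t not in (0, 1):
                raise GoGValidationError(f"label {t} not binary")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise GoGValidationError(f"duplicate pair {key}")
            seen.add(key)

    @property
    def n_pos(self) -> int:
        return sum(t for _, _, t in self.pairs)

    @property
    def n_neg(self) -> int:
        return len(self.pairs) - self.n_pos

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(n,2) index pairs and (n,) labels."""
        if not self.pairs:
            return np.empty((0, 2), dtype=np.intp), np.empty(0, dtype=np.intp)
        arr = np.asarray(self.pairs, dtype=np.intp)
        return arr[:, :2], arr[:, 2]


@dataclass
class GoGStats:
    n_compounds: int
    n_edges: int
    n_pairs: int
    density: float
    mean_internal_size: float
    mean_external_degree: float
    degree_histogram: dict[int, int]


def build_gog(
    compounds: Sequence[InternalGraph], edges: Iterable[tuple[str, str]]
) -> GoG:
    """Assemble a validated GoG from compounds and an id-level edge list.

    Edges are symmetrized and deduplicated; endpoints must name existing
    compound ids and self-loops are rejected.
    """
    ids = [c.graph_id for c in compounds]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateCompoundError(f"duplicate compound ids: {dup}")
    index = {gid: i for i, gid in enumerate(ids)}
    edge_set: set[tuple[int, int]] = set()
    for a, b in edges:
        if a not in index:
            raise UnknownCompoundError(f"edge endpoint {a!r} is not a known compound id")
        if b not in index:
            raise UnknownCompoundError(f"edge endpoint {b!r} is not a known compound id")
        i, j = index[a], index[b]
        if i == j:
            raise SelfLoopError(f"self-loop edge on compound {a!r}")
        edge_set.add((min(i, j), max(i, j)))
    adjacency: list[list[int]] = [[] for _ in compounds]
    for i, j in sorted(edge_set):
        adjacency[i].append(j)
        adjacency[j].append(i)
    return GoG(compounds=list(compounds), external_adjacency=adjacency)


def gog_stats(gog: GoG) -> GoGStats:
    """Network-level summary: pair count, link density, size/degree means."""
    n = gog.n_compounds
    if n < 2:
        raise GoGValidationError("density undefined for fewer than 2 compounds")
    n_edges = len(gog.external_edges())
    n_pairs = n * (n - 1) // 2
    degrees = [len(nbrs) for nbrs in gog.external_adjacency]
    hist: dict[int, int] = {}
    for d in degrees:
        hist[d] = hist.get(d, 0) + 1
    return GoGStats(
        n_compounds=n,
        n_edges=n_edges,
        n_pairs=n_pairs,
        density=n_edges / n_pairs,
        mean_internal_size=float(np.mean([c.n_atoms for c in gog.compounds])),
        mean_external_degree=float(np.mean(degrees)),
        degree_histogram=hist,
    )


def edge_arrays(adjacency: Sequence[Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
    """Directed (src, dst) arrays covering both directions of each edge.

    Message passing sums ``state[src]`` into ``dst``; an empty adjacency
    yields empty arrays.
    """
    src, dst = [], []
    for i, nbrs in enumerate(adjacency):
        for j in nbrs:
            src.append(j)
            dst.append(i)
    return np.asarray(src, dtype=np.intp), np.asarray(dst, dtype=np.intp)
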