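"""Synthetic graph-of-graphs benchmark generator.

Real chemical networks differ in link density and in the weight of the
degree-distribution tail, and links correlate both with molecular
substructure and with network communities.  The generator emulates exactly
these axes with a planted-factor model:

- every compound is a random connected molecular graph (spanning tree plus
  extra edges, atom degrees capped at 4) over a small element alphabet;
- a fraction of compounds carries a planted *motif*: a labeled N–O–S
  triangle (never present otherwise), giving an internal-structure signal;
- compounds belong to communities; within-community pairs link with a
  higher base rate than between-community pairs (``p_in`` vs ``p_out``),
  giving an external-structure signal;
- a pair in which both compounds carry the motif has its link probability
  multiplied by ``motif_boost``;
- probabilities are globally rescaled so the expected link density hits
  ``target_density``; the ``powerlaw`` degree model additionally biases
  pair probabilities by per-compound weights drawn from a discrete power
  law with exponent ``gamma``, producing heavy-tailed degree sequences.

Setting ``motif_boost=1`` removes all internal signal; ``p_in == p_out``
removes all community signal — the null regimes in which every predictor
should fall to chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gog import AtomSignature, GoG, InternalGraph, build_gog

NOMINAL_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
MOTIF_ELEMENTS = ("N", "O", "S")
MAX_DEGREE = 4  # valence cap for generated molecules


@dataclass
class SyntheticSpec:
    n_compounds: int = 300
    atom_alphabet: tuple[str, ...] = ("C", "N", "O", "S")
    size_range: tuple[int, int] = (8, 24)
    max_atoms: int = 64
    motif_fraction: float = 0.5
    n_communities: int = 3
    community_weights: tuple[float, ...] | None = None
    p_in: float = 4.0
    p_out: float = 1.0
    motif_boost: float = 1.0
    degree_model: str = "bernoulli"
    powerlaw_gamma: float = 2.5
    target_density: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.motif_fraction <= 1.0:
            raise ValueError("motif_fraction must be a probability")
        if not 0.0 < self.target_density <= 1.0:
            raise ValueError(f"target density {self.target_density} infeasible")
        if self.degree_model not in ("bernoulli", "powerlaw"):
            raise ValueError(f"unknown degree model {self.degree_model!r}")
        if self.size_range[0] < 1 or self.size_range[1] > self.max_atoms:
            raise ValueError("size_range outside [1, max_atoms]")
        if self.community_weights is None:
            self.community_weights = tuple([1.0 / self.n_communities] * self.n_communities)


@dataclass
class GroundTruth:
    community: np.ndarray
    motif: np.ndarray
    link_prob: np.ndarray = field(repr=False)  # upper-triangle pair probabilities


def _signature(element: str, degree: int, aromatic: bool = False) -> AtomSignature:
    val = NOMINAL_VALENCE.get(element, 4)
    return AtomSignature(
        element=element,
        valence=val,
        hydrogen_count=max(val - degree, 0),
        degree=degree,
        aromatic=aromatic,
    )


def _completes_motif_triangle(elements, adj, u, v) -> bool:
    for w in adj[u] & adj[v]:
        if {elements[u], elements[v], elements[w]} == set(MOTIF_ELEMENTS):
            return True
    return False


def gen_internal_graph(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    motif: bool = False,
    graph_id: str = "g",
) -> InternalGraph:
    """Random connected molecule; motif-bearing ones contain the N–O–S triangle.

    Non-motif molecules are guaranteed never to contain that triangle (the
    spanning tree is triangle-free and offending extra edges are rejected).
    """
    lo, hi = spec.size_range
    n = int(rng.integers(lo, hi + 1))
    if motif:
        n = max(n, 3)
    elements: list[str] = []
    adj: list[set[int]] = [set() for _ in range(n)]
    if motif:
        elements.extend(MOTIF_ELEMENTS)
        adj[0] |= {1, 2}
        adj[1] |= {0, 2}
        adj[2] |= {0, 1}
        start = 3
    else:
        elements.append(str(rng.choice(spec.atom_alphabet)))
        start = 1
    while len(elements) < n:
        elements.append(str(rng.choice(spec.atom_alphabet)))
    # spanning construction: each new atom bonds to an existing atom with
    # spare valence (one always exists: a tree's total degree is 2(k-1) < 4k)
    for k in range(start, n):
        candidates = [m for m in range(k) if len(adj[m]) < MAX_DEGREE]
        m = int(rng.choice(candidates))
        adj[k].add(m)
        adj[m].add(k)
    # extra edges up to valence limits
    for _ in range(int(rng.integers(0, max(n // 2, 1) + 1))):
        u, v = rng.integers(0, n, size=2)
        u, v = int(u), int(v)
        if u == v or v in adj[u]:
            continue
        if len(adj[u]) >= MAX_DEGREE or len(adj[v]) >= MAX_DEGREE:
            continue
        if not motif and _completes_motif_triangle(elements, adj, u, v):
            continue
        adj[u].add(v)
        adj[v].add(u)
    adjacency = [sorted(s) for s in adj]
    atoms = [
        _signature(elements[k], len(adjacency[k]), aromatic=(motif and k < 3))
        for k in range(n)
    ]
    return InternalGraph(graph_id=graph_id, atoms=atoms, adjacency=adjacency)


def _pair_factors(spec: SyntheticSpec, community, motif) -> np.ndarray:
    """Upper-triangle relative link propensity for every compound pair."""
    n = spec.n_compounds
    iu, ju = np.triu_indices(n, k=1)
    f = np.where(community[iu] == community[ju], spec.p_in, spec.p_out).astype(float)
    f[motif[iu] & motif[ju]] *= spec.motif_boost
    return f


def _calibrate_probabilities(f: np.ndarray, target_edges: float) -> np.ndarray:
    """Scale relative propensities so expected edge count hits the target.

    Probabilities are capped at 1, which biases a naive linear rescaling
    downward under heavy-tailed weights; the scale is therefore solved by
    bisection on the monotone map s -> sum(min(f*s, 1)).
    """
    if target_edges > np.count_nonzero(f):
        raise ValueError("target density infeasible for the given factors")
    lo, hi = 0.0, 1.0 / f[f > 0].min()
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.minimum(f * mid, 1.0).sum() < target_edges:
            lo = mid
        else:
            hi = mid
    return np.minimum(f * hi, 1.0)


def gen_gog(spec: SyntheticSpec) -> tuple[GoG, GroundTruth]:
    """Draw a GoG and its ground truth from the planted-factor model."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    community = rng.choice(spec.n_communities, size=n, p=spec.community_weights)
    motif = rng.random(n) < spec.motif_fraction
    compounds = [
        gen_internal_graph(rng, spec, motif=bool(motif[i]), graph_id=f"c{i:05d}")
        for i in range(n)
    ]
    f = _pair_factors(spec, community, motif)
    if spec.degree_model == "powerlaw":
        # inverse-CDF discrete power law, truncated at n-1
        u = rng.random(n)
        w = np.minimum(np.floor(u ** (-1.0 / (spec.powerlaw_gamma - 1.0))), n - 1)
        iu, ju = np.triu_indices(n, k=1)
        f = f * w[iu] * w[ju]
    n_pairs = n * (n - 1) // 2
    p = _calibrate_probabilities(f, spec.target_density * n_pairs)
    draw = rng.random(n_pairs) < p
    iu, ju = np.triu_indices(n, k=1)
    edges = [
        (compounds[i].graph_id, compounds[j].graph_id)
        for i, j in zip(iu[draw], ju[draw])
    ]
    gog = build_gog(compounds, edges)
    return gog, GroundTruth(community=community, motif=motif, link_prob=p)
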