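import numpy as np
import pytest

from gognn.gog import AtomSignature, InternalGraph, build_gog


def sig(element="C", degree=0, aromatic=False):
    val = {"C": 4, "N": 3, "O": 2, "S": 2}.get(element, 4)
    return AtomSignature(
        element=element,
        valence=val,
        hydrogen_count=max(val - degree, 0),
        degree=degree,
        aromatic=aromatic,
    )


def molecule(graph_id, elements, bonds):
    """Build a small molecule from element symbols and bond index pairs."""
    adjacency = [[] for _ in elements]
    for k, m in bonds:
        adjacency[k].append(m)
        adjacency[m].append(k)
    adjacency = [sorted(a) for a in adjacency]
    atoms = [sig(e, len(adjacency[i])) for i, e in enumerate(elements)]
    return InternalGraph(graph_id=graph_id, atoms=atoms, adjacency=adjacency)


@pytest.fixture
def single_atom():
    return molecule("m0", ["C"], [])


@pytest.fixture
def path3():
    """3-atom path C-N-O."""
    return molecule("p3", ["C", "N", "O"], [(0, 1), (1, 2)])


@pytest.fixture
def star4():
    """4-atom star: central C bonded to N, O, S."""
    return molecule("s4", ["C", "N", "O", "S"], [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def small_gog():
    """5 distinct small molecules with a 4-edge external network."""
    mols = [
        molecule("a", ["C"], []),
        molecule("b", ["C", "N"], [(0, 1)]),
        molecule("c", ["C", "N", "O"], [(0, 1), (1, 2)]),
        molecule("d", ["C", "O", "S"], [(0, 1), (0, 2)]),
        molecule("e", ["N", "O", "C", "C"], [(0, 1), (1, 2), (2, 3)]),
    ]
    return build_gog(mols, [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])


def random_molecule(rng, n_atoms, graph_id="r"):
    """Random connected molecule for property tests (degree-capped at 4)."""
    elements = [str(rng.choice(["C", "N", "O", "S"])) for _ in range(n_atoms)]
    bonds = []
    deg = [0] * n_atoms
    for k in range(1, n_atoms):
        options = [m for m in range(k) if deg[m] < 4]
        m = int(rng.choice(options))
        bonds.append((k, m))
        deg[k] += 1
        deg[m] += 1
    return molecule(graph_id, elements, bonds)
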