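"""Internal (molecular) convolution: oracle equivalence, invariances, gradients."""

import numpy as np
import pytest

from gognn.autodiff import Tensor
from gognn.gog import InternalGraph
from gognn.internal import (
    AtomEmbeddingTable,
    InternalConvParams,
    degree_bucket,
    internal_convolve,
    internal_convolve_packed,
    internal_step,
    pack_graphs,
)

from conftest import molecule, random_molecule, sig


def oracle_step(states, adjacency, W, M, activation):
    """Straight-line per-atom reimplementation of one convolution update."""
    out = []
    for k, nbrs in enumerate(adjacency):
        b = degree_bucket(len(nbrs))
        z = W[b] @ states[k]
        for m in nbrs:
            z = z + M[b] @ states[m]
        out.append(activation(z))
    return np.array(out)


def oracle_convolve(graph, v0, params):
    """Explicit-loop recomputation of the pooled compound vector."""
    act = {"relu": lambda z: np.maximum(z, 0), "identity": lambda z: z}[params.activation]
    states = np.array(v0, dtype=float)
    total = states.copy()
    for t in range(params.n_steps):
        W = params.W[t].data
        M = params.M[t].data
        states = oracle_step(states, graph.adjacency, W, M, act)
        total += states
    g = np.zeros(states.shape[1])
    for k in range(len(graph.atoms)):
        e = np.exp(total[k] - total[k].max())
        g += e / e.sum()
    return g


class TestInternalStep:
    def test_isolated_atom_zero_weights_gives_zero(self, single_atom):
        params = InternalConvParams(dim=3, n_steps=1, seed=0)
        for t in params.W + params.M:
            t.data[:] = 0.0
        out = internal_step(np.ones((1, 3)), single_atom, params, 0)
        assert np.array_equal(out.data, np.zeros((1, 3)))

    def test_identity_weights_sum_self_and_neighbor(self):
        mol = molecule("e2", ["C", "N"], [(0, 1)])
        params = InternalConvParams(dim=2, n_steps=1, activation="identity")
        for t in params.W + params.M:
            t.data[:] = np.eye(2)
        states = np.array([[1.0, 2.0], [10.0, 20.0]])
        out = internal_step(states, mol, params, 0)
        assert np.allclose(out.data, [[11.0, 22.0], [11.0, 22.0]])

    def test_three_atom_path_matches_oracle(self, path3):
        rng = np.random.default_rng(7)
        params = InternalConvParams(dim=2, n_steps=1, seed=7)
        states = rng.normal(size=(3, 2))
        out = internal_step(states, path3, params, 0)
        expected = oracle_step(
            states, path3.adjacency, params.W[0].data, params.M[0].data,
            lambda z: np.maximum(z, 0),
        )
        assert np.allclose(out.data, expected, atol=1e-6)

    def test_step_index_out_of_range(self, path3):
        params = InternalConvParams(dim=2, n_steps=1)
        with pytest.raises(ValueError):
            internal_step(np.zeros((3, 2)), path3, params, 1)

    def test_state_length_mismatch(self, path3):
        params = InternalConvParams(dim=2, n_steps=1)
        with pytest.raises(ValueError):
            internal_step(np.zeros((2, 2)), path3, params, 0)


class TestInternalConvolve:
    def test_single_atom_softmax_normalization(self, single_atom):
        table = AtomEmbeddingTable(single_atom.atoms, dim=4, seed=1)
        params = InternalConvParams(dim=4, n_steps=2, seed=1)
        g = internal_convolve(single_atom, table, params)
        assert g.data.shape == (1, 4)
        assert np.isclose(g.data.sum(), 1.0)

    @pytest.mark.parametrize("n_atoms", [2, 5, 9])
    def test_components_sum_to_atom_count(self, n_atoms):
        rng = np.random.default_rng(n_atoms)
        mol = random_molecule(rng, n_atoms)
        table = AtomEmbeddingTable(mol.atoms, dim=6, seed=2)
        params = InternalConvParams(dim=6, n_steps=2, seed=3)
        g = internal_convolve(mol, table, params)
        assert np.isclose(g.data.sum(), n_atoms, atol=1e-9)

    def test_star_graph_matches_loop_oracle(self, star4):
        table = AtomEmbeddingTable(star4.atoms, dim=3, seed=11)
        params = InternalConvParams(dim=3, n_steps=2, seed=11)
        g = internal_convolve(star4, table, params)
        v0 = table.weights.data[table.rows_for(star4.atoms)]
        assert np.allclose(g.data[0], oracle_convolve(star4, v0, params), atol=1e-6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        mol = random_molecule(rng, 7, "perm")
        perm = rng.permutation(7)
        inv = np.argsort(perm)
        adj_p = [sorted(int(perm[m]) for m in mol.adjacency[int(inv[k])]) for k in range(7)]
        mol_p = InternalGraph(
            "perm2",
            [mol.atoms[int(inv[k])] for k in range(7)],
            adj_p,
        )
        table = AtomEmbeddingTable(mol.atoms, dim=5, seed=6)
        params = InternalConvParams(dim=5, n_steps=3, seed=6)
        g1 = internal_convolve(mol, table, params)
        g2 = internal_convolve(mol_p, table, params)
        assert np.allclose(g1.data, g2.data, atol=1e-6)

    def test_isomorphic_graphs_same_representation(self):
        m1 = molecule("i1", ["C", "N", "O"], [(0, 1), (1, 2)])
        m2 = molecule("i2", ["O", "N", "C"], [(0, 1), (1, 2)])  # reversed path
        table = AtomEmbeddingTable(m1.atoms, dim=4, seed=9)
        params = InternalConvParams(dim=4, n_steps=2, seed=9)
        g1 = internal_convolve(m1, table, params)
        g2 = internal_convolve(m2, table, params)
        assert np.allclose(g1.data, g2.data, atol=1e-6)

    def test_unseen_signature_falls_back(self, path3, caplog):
        table = AtomEmbeddingTable(path3.atoms, dim=3, seed=0)
        rows = table.rows_for([sig("P", 0)])
        assert rows[0] == table.fallback_row


class TestGradients:
    def test_finite_difference_on_five_atom_molecule(self):
        """Backpropagated dL/dW, dL/dM, dL/d(embeddings) match central
        finite differences to 1e-4 relative error."""
        rng = np.random.default_rng(12)
        mol = random_molecule(rng, 5, "g5")
        table = AtomEmbeddingTable(mol.atoms, dim=3, seed=12)
        params = InternalConvParams(dim=3, n_steps=2, seed=13)
        packed = pack_graphs([mol], table)
        target = rng.normal(size=(1, 3))

        def loss_value():
            g = internal_convolve_packed(packed, table, params)
            return ((g.data - target) ** 2).sum()

        def loss_tensor():
            g = internal_convolve_packed(packed, table, params)
            diff = g + Tensor(-target)
            return (diff * diff).sum()

        loss = loss_tensor()
        loss.backward()
        eps = 1e-6
        for tensor in [table.weights, *params.W, *params.M]:
            flat = tensor.data.ravel()
            grad = tensor.grad.ravel()
            idx = rng.choice(flat.size, size=min(8, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_value()
                flat[i] = orig - eps
                lm = loss_value()
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)
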