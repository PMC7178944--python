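"""External (inter-compound) convolution: oracle equivalence, locality, gradients."""

import numpy as np
import pytest

from gognn.autodiff import Tensor
from gognn.external import ExternalConvParams, external_convolve, gog_message_adjacency


def softmax(z):
    e = np.exp(z - z.max())
    return e / e.sum()


def oracle_external(g_vectors, adjacency, params):
    """Explicit-loop recomputation of the refined representations."""
    f = {"softmax": softmax, "relu": lambda z: np.maximum(z, 0), "identity": lambda z: z}[
        params.f_activation
    ]
    states = np.array(g_vectors, dtype=float)
    total = states.copy()
    for l in range(params.n_steps):
        U, V = params.U[l].data, params.V[l].data
        new = []
        for i, nbrs in enumerate(adjacency):
            z = U @ states[i]
            for m in nbrs:
                z = z + V @ states[m]
            new.append(f(z))
        states = np.array(new)
        total += states
    return np.array([softmax(row) for row in total])


def cycle_adjacency(n):
    return [[(i - 1) % n, (i + 1) % n] for i in range(n)]


class TestExternalConvolve:
    def test_no_steps_is_softmax_of_input(self):
        params = ExternalConvParams(dim=3, n_steps=0)
        g = np.random.default_rng(0).normal(size=(4, 3))
        h = external_convolve(g, params, [[] for _ in range(4)])
        assert np.allclose(h.data.sum(axis=1), 1.0)
        assert np.allclose(h.data, np.array([softmax(r) for r in g]))

    def test_isolated_node_zero_weights_uniform(self):
        params = ExternalConvParams(dim=4, n_steps=1)
        params.U[0].data[:] = 0.0
        g = np.random.default_rng(1).normal(size=(1, 4))
        h = external_convolve(g, params, [[]])
        # step output f(0) is uniform; pooled softmax stays normalized
        assert np.isclose(h.data.sum(), 1.0)

    def test_four_node_cycle_matches_loop_oracle(self):
        rng = np.random.default_rng(13)
        params = ExternalConvParams(dim=3, n_steps=2, seed=13)
        g = rng.normal(size=(4, 3))
        adj = cycle_adjacency(4)
        h = external_convolve(g, params, adj)
        assert np.allclose(h.data, oracle_external(g, adj, params), atol=1e-6)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        params = ExternalConvParams(dim=5, n_steps=3, seed=2)
        h = external_convolve(rng.normal(size=(6, 5)), params, cycle_adjacency(6))
        assert np.allclose(h.data.sum(axis=1), 1.0, atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        n = 6
        params = ExternalConvParams(dim=4, n_steps=2, seed=3)
        g = rng.normal(size=(n, 4))
        adj = cycle_adjacency(n)
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        adj_p = [sorted(int(perm[m]) for m in adj[int(inv[i])]) for i in range(n)]
        h1 = external_convolve(g, params, adj)
        h2 = external_convolve(g[inv], params, adj_p)
        assert np.allclose(h2.data, h1.data[inv], atol=1e-10)

    def test_locality_on_path_graph(self):
        """With L steps, h_i only depends on compounds within distance L."""
        n, L = 7, 2
        adj = [[j for j in (i - 1, i + 1) if 0 <= j < n] for i in range(n)]
        params = ExternalConvParams(dim=3, n_steps=L, seed=4)
        rng = np.random.default_rng(4)
        g = rng.normal(size=(n, 3))
        h_before = external_convolve(g, params, adj).data.copy()
        g2 = g.copy()
        g2[6] += 5.0  # distance 6 from node 0 > L
        h_after = external_convolve(g2, params, adj).data
        assert np.allclose(h_after[0], h_before[0], atol=1e-12)
        assert not np.allclose(h_after[5], h_before[5])  # within distance L of node 6

    def test_adjacency_index_out_of_range(self):
        params = ExternalConvParams(dim=2, n_steps=1)
        with pytest.raises(ValueError):
            external_convolve(np.zeros((2, 2)), params, [[5], [0]])

    def test_dimension_mismatch(self):
        params = ExternalConvParams(dim=3, n_steps=1)
        with pytest.raises(ValueError):
            external_convolve(np.zeros((2, 2)), params, [[], []])


class TestMessageAdjacency:
    def test_edge_subset_symmetrized(self, small_gog):
        adj = gog_message_adjacency(small_gog, [(0, 1), (1, 0), (2, 3)])
        assert adj[0] == [1] and adj[1] == [0]
        assert adj[2] == [3] and adj[3] == [2]
        assert adj[4] == []

    def test_none_uses_full_adjacency(self, small_gog):
        assert gog_message_adjacency(small_gog, None) is small_gog.external_adjacency


class TestGradients:
    def test_finite_difference_on_U_V(self):
        rng = np.random.default_rng(21)
        params = ExternalConvParams(dim=3, n_steps=2, seed=21)
        g0 = rng.normal(size=(5, 3))
        adj = cycle_adjacency(5)
        target = rng.normal(size=(5, 3))

        def loss_value():
            return ((external_convolve(g0, params, adj).data - target) ** 2).sum()

        def loss_tensor():
            diff = external_convolve(g0, params, adj) + Tensor(-target)
            return (diff * diff).sum()

        loss = loss_tensor()
        loss.backward()
        eps = 1e-6
        for tensor in [*params.U, *params.V]:
            flat = tensor.data.ravel()
            grad = tensor.grad.ravel()
            for i in rng.choice(flat.size, size=6, replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_value()
                flat[i] = orig - eps
                lm = loss_value()
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-9)
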