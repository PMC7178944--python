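"""Negative sampling, splits, and the optimization loop."""

import numpy as np
import pytest

from gognn.gog import build_gog, gog_stats
from gognn.model import ModelParams
from gognn.predictor import cross_entropy_loss
from gognn.training import (
    InsufficientNonEdgesError,
    Split,
    TrainConfig,
    make_split,
    sample_negatives,
    train,
)
from gognn.external import gog_message_adjacency, external_convolve
from gognn.autodiff import softmax_rows, Tensor
from gognn.internal import internal_convolve_packed

from conftest import molecule, random_molecule


def er_gog(n, p, seed, mol_atoms=3):
    rng = np.random.default_rng(seed)
    mols = [random_molecule(rng, mol_atoms, f"m{i}") for i in range(n)]
    edges = [
        (f"m{i}", f"m{j}")
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return build_gog(mols, edges)


class TestSampleNegatives:
    def test_complete_graph_has_no_negatives(self):
        gog = er_gog(4, 1.1, 0)  # p > 1: complete
        with pytest.raises(InsufficientNonEdgesError):
            sample_negatives(gog, 1, seed=0)

    def test_same_seed_same_sample(self):
        gog = er_gog(15, 0.2, 1)
        assert sample_negatives(gog, 10, seed=7) == sample_negatives(gog, 10, seed=7)

    def test_sampled_pairs_avoid_edges_and_exclusions(self):
        gog = er_gog(20, 0.3, 2)
        exclude = {(0, 5), (3, 9)}
        sample = sample_negatives(gog, 50, exclude=exclude, seed=3)
        assert len(sample) == 50
        assert len(set(sample)) == 50
        edge_set = gog.edge_set()
        for i, j in sample:
            assert i < j
            assert (i, j) not in edge_set
            assert (i, j) not in exclude

    def test_uniformity_over_allowed_pairs(self):
        """Each allowed non-edge appears with roughly equal frequency."""
        gog = er_gog(8, 0.25, 4)
        allowed = [
            (i, j)
            for i in range(8)
            for j in range(i + 1, 8)
            if (i, j) not in gog.edge_set()
        ]
        counts = {p: 0 for p in allowed}
        for s in range(300):
            for p in sample_negatives(gog, 5, seed=s):
                counts[p] += 1
        freqs = np.array(list(counts.values()), dtype=float)
        expected = 300 * 5 / len(allowed)
        assert np.all(np.abs(freqs - expected) < 6 * np.sqrt(expected))


class TestMakeSplit:
    def test_train_and_test_pairs_disjoint(self):
        gog = er_gog(30, 0.3, 5)
        split = make_split(gog, 40, 40, {"n_test_pos": 20, "n_test_neg": 60}, seed=6)
        train_set = {(min(i, j), max(i, j)) for i, j, _ in split.train.pairs}
        test_set = {(min(i, j), max(i, j)) for i, j, _ in split.test.pairs}
        assert not train_set & test_set
        assert split.train.n_pos == 40 and split.train.n_neg == 40
        assert split.test.n_pos == 20 and split.test.n_neg == 60
        edge_set = gog.edge_set()
        for i, j, t in split.train.pairs + split.test.pairs:
            assert ((min(i, j), max(i, j)) in edge_set) == bool(t)
        assert set(split.message_edges) == {
            (i, j) for i, j, t in split.train.pairs if t == 1
        }

    def test_imbalance_preserving_test_fraction(self):
        gog = er_gog(80, 0.094, 7)
        density = gog_stats(gog).density
        split = make_split(gog, 50, 50, 1000, seed=8)
        frac = split.test.n_pos / len(split.test.pairs)
        assert frac == pytest.approx(density, abs=2e-3)

    def test_seed_determinism(self):
        gog = er_gog(25, 0.3, 9)
        s1 = make_split(gog, 30, 30, {"n_test_pos": 10, "n_test_neg": 30}, seed=10)
        s2 = make_split(gog, 30, 30, {"n_test_pos": 10, "n_test_neg": 30}, seed=10)
        assert s1.train.pairs == s2.train.pairs
        assert s1.test.pairs == s2.test.pairs

    def test_infeasible_positive_count(self):
        gog = er_gog(10, 0.1, 11)
        with pytest.raises(Exception):
            make_split(gog, 10_000, 10, {"n_test_pos": 1, "n_test_neg": 1}, seed=0)


def memorization_fixture(seed=0):
    gog = er_gog(10, 0.35, seed, mol_atoms=4)
    edges = gog.external_edges()
    pos = edges[:4]
    neg = sample_negatives(gog, 4, seed=seed)
    train_set = [(i, j, 1) for i, j in pos] + [(i, j, 0) for i, j in neg]
    from gognn.gog import LinkDataset

    split = Split(
        train=LinkDataset(train_set), test=LinkDataset([], role="test"), message_edges=pos
    )
    return gog, split


class TestTrain:
    def test_same_seed_identical_history(self):
        gog, split = memorization_fixture(1)
        cfg = TrainConfig(d=8, T=1, L=1, epochs=3, batch_size=8, seed=4,
                          validation_fraction=0.0)
        _, h1 = train(gog, split, cfg)
        _, h2 = train(gog, split, cfg)
        assert h1 == h2

    def test_chance_level_initial_loss(self):
        """Summed loss of an untrained model on a balanced batch is about
        n*ln(2): softmax outputs start near uniform."""
        gog, split = memorization_fixture(2)
        cfg = TrainConfig(d=8, T=1, L=1, epochs=0, batch_size=8, seed=5,
                          validation_fraction=0.0)
        model, _ = train(gog, split, cfg)
        pairs, labels = split.train.arrays()
        adj = gog_message_adjacency(gog, split.message_edges)
        probs = model.predict_proba_pairs(adj, pairs)
        loss = cross_entropy_loss(probs, labels)
        assert loss == pytest.approx(len(labels) * np.log(2), rel=0.2)

    def test_loss_history_eventually_decreasing(self):
        gog, split = memorization_fixture(3)
        cfg = TrainConfig(d=8, T=1, L=1, epochs=120, batch_size=8, seed=6,
                          validation_fraction=0.0, dropout_rate=0.0)
        _, history = train(gog, split, cfg)
        assert history[-1]["loss"] < history[0]["loss"] / 10

    def test_divergence_aborts(self):
        gog, split = memorization_fixture(4)
        cfg = TrainConfig(d=4, T=1, L=1, epochs=2, batch_size=8, seed=7,
                          learning_rate=1e150, validation_fraction=0.0)
        with pytest.raises(FloatingPointError):
            train(gog, split, cfg)


class TestModes:
    def test_internal_only_is_softmax_of_internal_conv(self, small_gog):
        model = ModelParams(small_gog, mode="internal_only", dim=6, seed=1)
        h = model.compound_representations([[] for _ in range(5)])
        g = internal_convolve_packed(model.packed, model.table, model.internal)
        assert np.allclose(h.data, softmax_rows(g).data, atol=1e-12)

    def test_embedding_only_uses_free_embeddings_and_external_conv(self, small_gog):
        model = ModelParams(small_gog, mode="embedding_only", dim=6, seed=2)
        adj = small_gog.external_adjacency
        h = model.compound_representations(adj)
        expected = external_convolve(Tensor(model.embeddings.data), model.external, adj)
        assert np.allclose(h.data, expected.data, atol=1e-12)
        assert model.table is None and model.internal is None

    def test_fingerprint_features_are_frozen(self, small_gog):
        model = ModelParams(small_gog, mode="fingerprint", dim=8,
                            fingerprint_bits=64, seed=3)
        h = model.compound_representations([[] for _ in range(5)])
        assert not h.requires_grad
        assert set(np.unique(h.data)) <= {0.0, 1.0}
        # only the predictor head is trainable
        names = {t.name for t in model.trainable()}
        assert all(n.startswith("P_") for n in names)

    def test_end_to_end_gradient_three_compounds(self):
        """Finite differences through internal conv -> external conv ->
        predictor -> summed cross-entropy, relative error <= 1e-3."""
        mols = [
            molecule("x", ["C", "N"], [(0, 1)]),
            molecule("y", ["O", "C"], [(0, 1)]),
            molecule("z", ["S"], []),
        ]
        gog = build_gog(mols, [("x", "y"), ("y", "z")])
        model = ModelParams(gog, mode="dual", dim=3, n_internal_steps=1,
                            n_external_steps=1, dropout_rate=0.0, seed=9)
        adj = gog.external_adjacency
        pairs = np.array([[0, 1], [0, 2]], dtype=np.intp)
        labels = np.array([1, 0])

        def loss_value():
            probs = model.predict_proba_pairs(adj, pairs)
            return cross_entropy_loss(probs, labels)

        loss = model.batch_loss(adj, pairs, labels, train_mode=False)
        loss.backward()
        rng = np.random.default_rng(0)
        eps = 1e-6
        for tensor in model.trainable():
            if tensor.grad is None:
                continue
            flat = tensor.data.ravel()
            grad = tensor.grad.ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss_value()
                flat[i] = orig - eps
                lm = loss_value()
                flat[i] = orig
                fd = (lp - lm) / (2 * eps)
                assert grad[i] == pytest.approx(fd, rel=1e-3, abs=1e-8)
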