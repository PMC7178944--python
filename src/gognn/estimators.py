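"""Estimator interface for the link-prediction models.

``DualGraphConv`` wraps end-to-end training of the dual graph convolutional
network (and its ablation modes) behind a scikit-learn-style surface:
hyperparameters in ``__init__`` (so ``get_params``/``set_params`` and grid
utilities work), data at ``fit``, fitted state in trailing-underscore
attributes.  The samples are compound-index *pairs*; the GoG container is
passed alongside them because every pair is scored in the context of the
whole graph.

``SimilarityIndexPredictor`` exposes the classical indices (common
neighbors, Jaccard, Katz) through the same surface so that every method can
be swapped into the same evaluation code.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .baselines import similarity_scores
from .evaluation import MetricsReport, evaluate_scores
from .external import gog_message_adjacency
from .gog import GoG, LinkDataset
from .training import Split, TrainConfig, train


class DualGraphConv(BaseEstimator):
    """Dual graph convolutional link predictor (and its ablations).

    Parameters mirror :class:`~gognn.training.TrainConfig`; ``mode`` selects
    the variant: ``dual``, ``internal_only``, ``embedding_only`` or
    ``fingerprint``.
    """

    def __init__(
        self,
        mode: str = "dual",
        d: int = 32,
        T: int = 1,
        L: int = 1,
        batch_size: int = 128,
        learning_rate: float = 0.001,
        epochs: int = 100,
        dropout_rate: float = 0.2,
        validation_fraction: float = 0.1,
        f_activation: str = "softmax",
        sigma_activation: str = "softmax",
        internal_activation: str = "relu",
        use_bias: bool = True,
        fingerprint_bits: int = 2048,
        fingerprint_radius: int = 2,
        random_state: int = 0,
    ):
        self.mode = mode
        self.d = d
        self.T = T
        self.L = L
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.dropout_rate = dropout_rate
        self.validation_fraction = validation_fraction
        self.f_activation = f_activation
        self.sigma_activation = sigma_activation
        self.internal_activation = internal_activation
        self.use_bias = use_bias
        self.fingerprint_bits = fingerprint_bits
        self.fingerprint_radius = fingerprint_radius
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            d=self.d,
            T=self.T,
            L=self.L,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            mode=self.mode,
            dropout_rate=self.dropout_rate,
            validation_fraction=self.validation_fraction,
            f_activation=self.f_activation,
            sigma_activation=self.sigma_activation,
            internal_activation=self.internal_activation,
            use_bias=self.use_bias,
            fingerprint_bits=self.fingerprint_bits,
            fingerprint_radius=self.fingerprint_radius,
            seed=self.random_state,
        )

    def fit(self, gog: GoG, pairs, labels, message_edges=None):
        """Train on labeled compound pairs.

        ``message_edges`` is the edge subset the external convolution may
        see; it defaults to the positive training pairs (never give it
        held-out links).
        """
        pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
        labels = np.asarray(labels, dtype=np.intp)
        if message_edges is None:
            message_edges = [tuple(p) for p, t in zip(pairs.tolist(), labels) if t == 1]
        dataset = LinkDataset(
            [(int(i), int(j), int(t)) for (i, j), t in zip(pairs.tolist(), labels)]
        )
        split = Split(train=dataset, test=LinkDataset([], role="test"),
                      message_edges=list(message_edges))
        self.model_, self.history_ = train(gog, split, self._config())
        self.gog_ = gog
        self.message_adjacency_ = gog_message_adjacency(gog, list(message_edges))
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, pairs) -> np.ndarray:
        """(n, 2) no-link / link probabilities in eval mode."""
        self._check_fitted()
        return self.model_.predict_proba_pairs(self.message_adjacency_, pairs)

    def decision_function(self, pairs) -> np.ndarray:
        return self.predict_proba(pairs)[:, 1]

    def predict(self, pairs) -> np.ndarray:
        return (self.decision_function(pairs) >= 0.5).astype(int)

    def evaluate(self, pairs, labels) -> MetricsReport:
        return evaluate_scores(self.decision_function(pairs), labels)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")


class SimilarityIndexPredictor(BaseEstimator):
    """Unsupervised link scoring by a classical similarity index."""

    def __init__(self, index: str = "katz", beta: float = 0.001):
        self.index = index
        self.beta = beta

    def fit(self, gog: GoG, pairs=None, labels=None, message_edges=None):
        """Record the scoring adjacency (training positives, or the full GoG).

        ``pairs``/``labels`` are accepted for interface symmetry: if given
        and ``message_edges`` is not, the positive pairs become the scoring
        edges.
        """
        if message_edges is None and pairs is not None and labels is not None:
            pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
            labels = np.asarray(labels)
            message_edges = [tuple(p) for p, t in zip(pairs.tolist(), labels) if t == 1]
        self.adjacency_ = gog_message_adjacency(gog, message_edges)
        return self

    def decision_function(self, pairs) -> np.ndarray:
        if not hasattr(self, "adjacency_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
        return similarity_scores(self.adjacency_, pairs, self.index, self.beta)

    def evaluate(self, pairs, labels) -> MetricsReport:
        return evaluate_scores(self.decision_function(pairs), labels)


def evaluate_on_split(estimator, gog: GoG, split: Split) -> MetricsReport:
    """Fit on the split's training pairs and score its test pairs."""
    train_pairs, train_labels = split.train.arrays()
    estimator.fit(gog, train_pairs, train_labels, message_edges=split.message_edges)
    test_pairs, test_labels = split.test.arrays()
    return evaluate_scores(estimator.decision_function(test_pairs), test_labels)
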