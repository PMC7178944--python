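"""Symmetric pairwise link predictor and cross-entropy loss.

A pair (i, j) is featurized symmetrically as

    (h_i + h_j) concat (h_i * h_j)

(elementwise sum and Hadamard product), fed through a ReLU MLP with hidden
sizes 128 and 64 and a 2-way output, and converted to link probabilities by
softmax.  Because the featurization is symmetric, p(i, j) == p(j, i) exactly
— the two orders produce the identical computation.

The training loss is the *summed* cross-entropy over pairs,
L = -sum_i log p_{t_i}.
"""

from __future__ import annotations

import logging

import numpy as np

from .autodiff import (
    Tensor,
    add_bias,
    concat_cols,
    dropout,
    matmul,
    relu,
    softmax_rows,
)

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-12


class PredictorParams:
    """MLP head: 2d -> hidden1 -> hidden2 -> 2, ReLU activations, biases.

    Dropout (default rate 0.2) is applied after each hidden ReLU in train
    mode only.  The convolution layers are bias-free; the MLP head carries
    biases as usual.
    """

    def __init__(
        self,
        dim: int,
        hidden1: int = 128,
        hidden2: int = 64,
        dropout_rate: float = 0.2,
        seed: int = 0,
        use_bias: bool = True,
    ):
        self.dim = dim
        self.dropout_rate = dropout_rate
        self.use_bias = use_bias
        rng = np.random.default_rng(seed)
        sizes = [(2 * dim, hidden1), (hidden1, hidden2), (hidden2, 2)]
        # He initialization: std = sqrt(2 / fan_in) for the ReLU layers
        self.weights = [
            Tensor(rng.normal(0, np.sqrt(2.0 / s[0]), s), requires_grad=True, name=f"P_W{i}")
            for i, s in enumerate(sizes)
        ]
        self.biases = [
            Tensor(np.zeros(s[1]), requires_grad=True, name=f"P_b{i}") for i, s in enumerate(sizes)
        ]

    def tensors(self) -> list[Tensor]:
        return [*self.weights, *(self.biases if self.use_bias else [])]


def pair_features(h_i: Tensor, h_j: Tensor) -> Tensor:
    """Symmetric pair featurization: sum block then Hadamard-product block."""
    if h_i.shape != h_j.shape:
        raise ValueError("pair feature inputs must have equal shape")
    return concat_cols(h_i + h_j, h_i * h_j)


def predictor_logits(
    features: Tensor,
    params: PredictorParams,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> Tensor:
    x = features
    for layer in range(3):
        x = matmul(x, params.weights[layer])
        if params.use_bias:
            x = add_bias(x, params.biases[layer])
        if layer < 2:
            x = relu(x)
            if train_mode and params.dropout_rate > 0:
                if rng is None:
                    raise ValueError("train-mode dropout requires an rng")
                x = dropout(x, params.dropout_rate, rng)
    if not np.all(np.isfinite(x.data)):
        raise FloatingPointError("non-finite activations in link predictor")
    return x


def predict_link_prob(
    h_i,
    h_j,
    params: PredictorParams,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """(p_no_link, p_link) rows for batched pair representations."""
    h_i = h_i if isinstance(h_i, Tensor) else Tensor(np.atleast_2d(h_i))
    h_j = h_j if isinstance(h_j, Tensor) else Tensor(np.atleast_2d(h_j))
    logits = predictor_logits(pair_features(h_i, h_j), params, train_mode, rng)
    return softmax_rows(logits).data


def cross_entropy_loss(prob_pairs, labels) -> float:
    """Summed cross-entropy -sum_i log p_{t_i} over labeled pairs.

    ``prob_pairs`` holds (p_0, p_1) rows; probabilities at 0 are clamped at
    1e-12 with a warning rather than producing an infinite loss.
    """
    probs = np.asarray(prob_pairs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.intp)
    if len(probs) != len(labels):
        raise ValueError("probabilities and labels differ in length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    p_true = probs[np.arange(len(labels)), labels]
    if np.any(p_true < PROB_FLOOR):
        logger.warning("clamping %d zero probabilities at %g", int((p_true < PROB_FLOOR).sum()), PROB_FLOOR)
        p_true = np.maximum(p_true, PROB_FLOOR)
    return float(-np.log(p_true).sum())
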