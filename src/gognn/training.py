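"""Negative sampling, train/test splits, and the end-to-end training loop.

Observed links are the only positives; negatives are uniformly sampled
unconnected pairs.  Test sets either use explicit positive/negative counts
or preserve the network's class imbalance (positive fraction equal to the
link density).  Message passing during training and evaluation sees
training-positive edges only, so test links never leak into the
representation.

Optimization is mini-batch Adam on the summed cross-entropy, updating every
trainable tensor including the atom embeddings.  With a validation fraction
> 0 the epoch with the best validation ROC-AUC is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import roc_auc
from .external import gog_message_adjacency
from .gog import GoG, GoGValidationError, LinkDataset
from .model import ModelParams

logger = logging.getLogger(__name__)


class InsufficientNonEdgesError(GoGValidationError):
    pass


@dataclass
class TrainConfig:
    """Hyperparameters for end-to-end training.

    Defaults follow the reference setting: Adam with learning rate 0.001,
    dropout 0.2, embedding dimension from {32, 62, 128}, convolution steps
    T and L from {1, 3, 5}, batch size from {64, 128, 256}.
    """

    d: int = 32
    T: int = 1
    L: int = 1
    batch_size: int = 128
    learning_rate: float = 0.001
    epochs: int = 100
    mode: str = "dual"
    dropout_rate: float = 0.2
    n_train_pos: int = 1000
    n_train_neg: int = 1000
    validation_fraction: float = 0.1
    f_activation: str = "softmax"
    sigma_activation: str = "softmax"
    internal_activation: str = "relu"
    use_bias: bool = True
    fingerprint_bits: int = 2048
    fingerprint_radius: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch size and epochs must be positive")


@dataclass
class Split:
    train: LinkDataset
    test: LinkDataset
    message_edges: list[tuple[int, int]] = field(default_factory=list)


class Adam:
    """Adaptive-moment SGD (Kingma & Ba) over a list of autodiff tensors."""

    def __init__(self, tensors, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.tensors = list(tensors)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(t.data) for t in self.tensors]
        self.v = [np.zeros_like(t.data) for t in self.tensors]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, p in enumerate(self.tensors):
            if p.grad is None:
                continue
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def zero_grad(self):
        for p in self.tensors:
            p.grad = None


# ----------------------------------------------------------------------
def _encode_pairs(pairs, n: int) -> np.ndarray:
    """Map unordered pairs (i<j) to unique integers below C(n,2)."""
    p = np.asarray(list(pairs), dtype=np.int64).reshape(-1, 2)
    i = np.minimum(p[:, 0], p[:, 1])
    j = np.maximum(p[:, 0], p[:, 1])
    return i * (2 * n - i - 1) // 2 + (j - i - 1)


def _decode_pairs(codes: np.ndarray, n: int) -> list[tuple[int, int]]:
    starts = np.array([i * (2 * n - i - 1) // 2 for i in range(n - 1)], dtype=np.int64)
    rows = np.searchsorted(starts, codes, side="right") - 1
    cols = codes - starts[rows] + rows + 1
    return [(int(i), int(j)) for i, j in zip(rows, cols)]


def sample_negatives(
    gog: GoG, n: int, exclude: set[tuple[int, int]] | None = None, seed: int = 0
) -> list[tuple[int, int]]:
    """Uniformly sample ``n`` distinct unconnected compound pairs.

    Samples are disjoint from the network's edges and from ``exclude``
    (unordered pairs); reproducible for a given seed.
    """
    nc = gog.n_compounds
    total = nc * (nc - 1) // 2
    forbidden = set(_encode_pairs(gog.external_edges(), nc).tolist()) if gog.external_edges() else set()
    if exclude:
        forbidden.update(_encode_pairs(exclude, nc).tolist())
    n_allowed = total - len(forbidden)
    if n > n_allowed:
        raise InsufficientNonEdgesError(
            f"requested {n} negatives but only {n_allowed} non-edges available"
        )
    rng = np.random.default_rng(seed)
    if total <= 2_000_000:
        allowed = np.setdiff1d(np.arange(total, dtype=np.int64), np.fromiter(forbidden, dtype=np.int64, count=len(forbidden)))
        codes = rng.choice(allowed, size=n, replace=False)
    else:  # rejection sampling for very large pair spaces
        chosen: set[int] = set()
        while len(chosen) < n:
            draw = rng.integers(0, total, size=2 * (n - len(chosen)) + 16)
            for c in draw:
                c = int(c)
                if c not in forbidden and c not in chosen:
                    chosen.add(c)
                    if len(chosen) == n:
                        break
        codes = np.fromiter(chosen, dtype=np.int64, count=n)
    return _decode_pairs(np.sort(codes), nc)


def make_split(
    gog: GoG,
    n_train_pos: int,
    n_train_neg: int,
    test_spec: dict | int,
    seed: int = 0,
) -> Split:
    """Sample a train/test split of labeled pairs.

    ``test_spec`` is either ``{"n_test_pos": ..., "n_test_neg": ...}`` or an
    integer total test size whose positive fraction matches the network link
    density (imbalance-preserving).  Training and test pair sets are
    disjoint; test negatives are disjoint from all positives and from
    training negatives.  ``message_edges`` holds the training positives.
    """
    rng = np.random.default_rng(seed)
    edges = gog.external_edges()
    if isinstance(test_spec, dict):
        n_test_pos = int(test_spec["n_test_pos"])
        n_test_neg = int(test_spec["n_test_neg"])
    else:
        n = gog.n_compounds
        density = len(edges) / (n * (n - 1) // 2)
        n_test_pos = max(1, round(test_spec * density))
        n_test_neg = int(test_spec) - n_test_pos
    if n_train_pos + n_test_pos > len(edges):
        raise GoGValidationError(
            f"need {n_train_pos}+{n_test_pos} positives but network has {len(edges)} edges"
        )
    order = rng.permutation(len(edges))
    train_pos = [edges[k] for k in order[:n_train_pos]]
    test_pos = [edges[k] for k in order[n_train_pos : n_train_pos + n_test_pos]]
    neg_seed = int(rng.integers(0, 2**31 - 1))
    negatives = sample_negatives(gog, n_train_neg + n_test_neg, seed=neg_seed)
    train_neg = negatives[:n_train_neg]
    test_neg = negatives[n_train_neg:]
    train = LinkDataset(
        [(i, j, 1) for i, j in train_pos] + [(i, j, 0) for i, j in train_neg], role="train"
    )
    test = LinkDataset(
        [(i, j, 1) for i, j in test_pos] + [(i, j, 0) for i, j in test_neg], role="test"
    )
    return Split(train=train, test=test, message_edges=list(train_pos))


# ----------------------------------------------------------------------
def train(gog: GoG, split: Split, config: TrainConfig) -> tuple[ModelParams, list[dict]]:
    """End-to-end training; returns fitted parameters and per-epoch history.

    Each history record holds the epoch's summed cross-entropy over all
    training pairs and, when a validation fraction is set, the validation
    ROC-AUC.  Training aborts with ``FloatingPointError`` on divergence.
    """
    rng = np.random.default_rng(config.seed)
    model = ModelParams(
        gog,
        mode=config.mode,
        dim=config.d,
        n_internal_steps=config.T,
        n_external_steps=config.L,
        dropout_rate=config.dropout_rate,
        hidden1=128,
        hidden2=64,
        f_activation=config.f_activation,
        sigma_activation=config.sigma_activation,
        internal_activation=config.internal_activation,
        use_bias=config.use_bias,
        fingerprint_bits=config.fingerprint_bits,
        fingerprint_radius=config.fingerprint_radius,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    pairs, labels = split.train.arrays()

    # held-out development fraction for model selection
    n_val = int(len(pairs) * config.validation_fraction)
    perm = rng.permutation(len(pairs))
    can_validate = n_val >= 2 and len(np.unique(labels[perm[:n_val]])) == 2
    if can_validate:
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
    else:
        val_idx, fit_idx = np.empty(0, dtype=np.intp), perm
    # the message graph must not contain held-out positives, otherwise
    # validation ROC rewards models that read links off the message graph
    msg_pairs = {(min(i, j), max(i, j)) for i, j in split.message_edges}
    val_pos = {
        (min(pairs[k][0], pairs[k][1]), max(pairs[k][0], pairs[k][1]))
        for k in val_idx
        if labels[k] == 1
    }
    msg_adj = gog_message_adjacency(gog, sorted(msg_pairs - val_pos))

    opt = Adam(model.trainable(), lr=config.learning_rate)
    drop_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
    history: list[dict] = []
    best_val, best_state = -np.inf, None
    for epoch in range(config.epochs):
        order = rng.permutation(fit_idx)
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            loss = model.batch_loss(msg_adj, pairs[batch], labels[batch], True, drop_rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        record = {"epoch": epoch, "loss": epoch_loss}
        if can_validate:
            val_probs = model.predict_proba_pairs(msg_adj, pairs[val_idx])[:, 1]
            record["val_roc_auc"] = roc_auc(val_probs, labels[val_idx])
            if record["val_roc_auc"] > best_val:
                best_val = record["val_roc_auc"]
                best_state = model.snapshot()
        history.append(record)
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, history
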