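"""Model parameter container and the mode-dependent forward pass.

Four model variants share the symmetric link-prediction head and differ in
how the per-compound representation ``h`` is produced:

- ``dual``           internal convolution then external convolution;
- ``internal_only``  internal convolution, ``h = softmax(g)`` (no network);
- ``embedding_only`` a free trainable vector per compound (relational
                     embedding, random init) refined by the external
                     convolution — no molecular structure is used;
- ``fingerprint``    frozen hashed Morgan fingerprint bits as ``h``; only
                     the predictor head is trained.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, cross_entropy_with_logits, gather_rows, softmax_rows
from .external import ExternalConvParams, external_convolve
from .gog import GoG
from .internal import (
    AtomEmbeddingTable,
    InternalConvParams,
    PackedAtoms,
    internal_convolve_packed,
    pack_graphs,
)
from .predictor import PredictorParams, pair_features, predictor_logits

MODES = ("dual", "internal_only", "embedding_only", "fingerprint")


class ModelParams:
    """All trainable tensors for one model variant."""

    def __init__(
        self,
        gog: GoG,
        mode: str = "dual",
        dim: int = 32,
        n_internal_steps: int = 1,
        n_external_steps: int = 1,
        dropout_rate: float = 0.2,
        hidden1: int = 128,
        hidden2: int = 64,
        f_activation: str = "softmax",
        sigma_activation: str = "softmax",
        internal_activation: str = "relu",
        use_bias: bool = True,
        fingerprint_bits: int = 2048,
        fingerprint_radius: int = 2,
        seed: int = 0,
    ):
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
        self.mode = mode
        self.dim = dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        seeds = rng.integers(0, 2**31 - 1, size=5)

        self.table: AtomEmbeddingTable | None = None
        self.internal: InternalConvParams | None = None
        self.external: ExternalConvParams | None = None
        self.embeddings: Tensor | None = None
        self.packed: PackedAtoms | None = None
        self.fixed_features: np.ndarray | None = None

        if mode in ("dual", "internal_only"):
            sigs = [s for c in gog.compounds for s in c.atoms]
            self.table = AtomEmbeddingTable(sigs, dim, seed=int(seeds[0]))
            self.internal = InternalConvParams(
                dim, n_internal_steps, activation=internal_activation, seed=int(seeds[1])
            )
            self.packed = pack_graphs(gog.compounds, self.table)
        if mode in ("dual", "embedding_only"):
            self.external = ExternalConvParams(
                dim,
                n_external_steps,
                f_activation=f_activation,
                sigma_activation=sigma_activation,
                seed=int(seeds[2]),
            )
        if mode == "embedding_only":
            emb_rng = np.random.default_rng(int(seeds[3]))
            self.embeddings = Tensor(
                emb_rng.normal(0, 0.1, (gog.n_compounds, dim)),
                requires_grad=True,
                name="compound_embeddings",
            )
        if mode == "fingerprint":
            from .baselines import fingerprint_mode_features

            self.fixed_features = fingerprint_mode_features(
                gog, radius=fingerprint_radius, nbits=fingerprint_bits
            )
            head_dim = fingerprint_bits
        else:
            head_dim = dim
        self.predictor = PredictorParams(
            head_dim,
            hidden1=hidden1,
            hidden2=hidden2,
            dropout_rate=dropout_rate,
            seed=int(seeds[4]),
            use_bias=use_bias,
        )

    # ------------------------------------------------------------------
    def trainable(self) -> list[Tensor]:
        out: list[Tensor] = []
        if self.table is not None:
            out.append(self.table.weights)
        if self.internal is not None:
            out.extend(self.internal.tensors())
        if self.external is not None:
            out.extend(self.external.tensors())
        if self.embeddings is not None:
            out.append(self.embeddings)
        out.extend(self.predictor.tensors())
        return out

    def compound_representations(self, message_adjacency: list[list[int]]) -> Tensor:
        """Full-graph forward pass producing h for every compound."""
        if self.mode == "fingerprint":
            return Tensor(self.fixed_features)
        if self.mode == "embedding_only":
            g = self.embeddings
        else:
            g = internal_convolve_packed(self.packed, self.table, self.internal)
        if self.mode == "internal_only":
            return softmax_rows(g)
        return external_convolve(g, self.external, message_adjacency)

    def pair_logits(
        self,
        h: Tensor,
        pairs: np.ndarray,
        train_mode: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        h_i = gather_rows(h, pairs[:, 0])
        h_j = gather_rows(h, pairs[:, 1])
        return predictor_logits(pair_features(h_i, h_j), self.predictor, train_mode, rng)

    def batch_loss(
        self,
        message_adjacency: list[list[int]],
        pairs: np.ndarray,
        labels: np.ndarray,
        train_mode: bool,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        h = self.compound_representations(message_adjacency)
        logits = self.pair_logits(h, pairs, train_mode, rng)
        return cross_entropy_with_logits(logits, labels)

    def predict_proba_pairs(
        self, message_adjacency: list[list[int]], pairs: np.ndarray
    ) -> np.ndarray:
        """(n_pairs, 2) link probabilities in eval mode (no dropout)."""
        h = self.compound_representations(message_adjacency)
        logits = self.pair_logits(h, np.asarray(pairs, dtype=np.intp))
        return softmax_rows(logits).data

    # -- checkpoint support --------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        return {t.name: t.data for t in self.trainable()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for t in self.trainable():
            if t.name not in arrays:
                raise KeyError(f"checkpoint missing tensor {t.name}")
            if arrays[t.name].shape != t.data.shape:
                raise ValueError(
                    f"tensor {t.name}: checkpoint shape {arrays[t.name].shape} "
                    f"!= model shape {t.data.shape}"
                )
            t.data = np.array(arrays[t.name], dtype=np.float64)

    def snapshot(self) -> dict[str, np.ndarray]:
        return {t.name: t.data.copy() for t in self.trainable()}
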