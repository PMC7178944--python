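"""Standard synthetic benchmark regimes for the dual graph convolution.

Three study conditions, mirroring the qualitative regimes of real chemical
networks:

``dense``
    n=300 compounds, target link density 0.09 with a power-law degree tail
    (gamma=2.2) — the dense, heavy-tailed regime (drug-interaction-like).
    Both internal signal (motif boost 5) and external signal (within- vs
    between-community rate 4:1) are planted; 1000 training positives.
    Expected ordering: dual convolution > {internal-only, Katz}.

``sparse``
    n=600 compounds at the extreme sparsity of a metabolite-reaction-like
    network.  Sparsity is scaled by *mean external degree* (1.70, the value
    implied by 5041 edges over 5920 compounds): link density is not
    scale-free, so carrying a degree-style sparsity to a smaller n preserves
    the phenomenon (too few links to learn from) where carrying the raw
    density would leave almost no edges at all.  Expected behavior: path-
    and embedding-based methods collapse toward chance; frozen fingerprint
    features stay best.

``null``
    No planted signal (motif boost 1, uniform community rates): every
    method should sit at chance.  The training fraction of edges is kept
    small because sampling training positives without replacement depletes
    the remaining (test) edges of heavily used compounds, which would
    otherwise anti-correlate test links with memorized per-compound
    "linkiness" — a transductive-split artifact, not a signal.

Each benchmark function retrains from scratch and returns mean test ROC-AUC
per method; seeds control every random choice.
"""

from __future__ import annotations

import numpy as np

from .estimators import DualGraphConv, SimilarityIndexPredictor, evaluate_on_split
from .gog import LinkDataset, build_gog, gog_stats
from .synthetic import SyntheticSpec, gen_gog
from .training import Split, make_split, sample_negatives

#: the three regimes' generator settings (everything except the seed)
DENSE_SPEC = dict(
    n_compounds=300, target_density=0.09, degree_model="powerlaw",
    powerlaw_gamma=2.2, motif_boost=5.0, p_in=4.0, p_out=1.0,
    motif_fraction=0.5,
)
#: metabolite-like sparsity scaled by mean external degree 1.70
SPARSE_SPEC = dict(
    n_compounds=600, target_density=1.70 / 599, degree_model="bernoulli",
    motif_boost=5.0, p_in=4.0, p_out=1.0, motif_fraction=0.5,
)
NULL_SPEC = dict(
    n_compounds=300, target_density=0.05, degree_model="bernoulli",
    motif_boost=1.0, p_in=1.0, p_out=1.0, motif_fraction=0.5,
)

#: shared model hyperparameters (reference setting: Adam, lr 0.001,
#: dropout 0.2, predictor 128/64); L=5 for the dual model in line with
#: external depth mattering most in dense networks
DUAL_KW = dict(mode="dual", d=32, T=1, L=5, batch_size=128, epochs=30)
INTERNAL_KW = dict(mode="internal_only", d=32, T=1, epochs=30, batch_size=128)
EMBEDDING_KW = dict(mode="embedding_only", d=32, L=1, epochs=100, batch_size=128)
FINGERPRINT_KW = dict(mode="fingerprint", epochs=100, batch_size=128)


def _mean(values):
    return float(np.mean(values))


def dense_benchmark(seeds=(1, 2, 3), progress=None) -> dict[str, float]:
    """Dense heavy-tailed regime: dual vs internal-only vs Katz.

    1000 training positives/negatives; imbalance-preserving 2000-pair test.
    Returns mean test ROC-AUC over the given seeds per method.
    """
    rocs: dict[str, list[float]] = {}
    for k in seeds:
        gog, _ = gen_gog(SyntheticSpec(seed=100 + k, **DENSE_SPEC))
        split = make_split(gog, 1000, 1000, 2000, seed=200 + k)
        for name, kw in (("dual", DUAL_KW), ("internal_only", INTERNAL_KW)):
            est = DualGraphConv(random_state=k, **kw)
            rocs.setdefault(name, []).append(evaluate_on_split(est, gog, split).roc_auc)
            if progress:
                progress(f"dense seed {k} {name}: {rocs[name][-1]:.3f}")
        katz = SimilarityIndexPredictor("katz")
        rocs.setdefault("katz", []).append(evaluate_on_split(katz, gog, split).roc_auc)
        if progress:
            progress(f"dense seed {k} katz: {rocs['katz'][-1]:.3f}")
    return {name: _mean(v) for name, v in rocs.items()}


def sparse_benchmark(seeds=(1, 2, 3), progress=None) -> dict[str, float]:
    """Extremely sparse regime: fingerprint vs embedding-only vs Katz.

    Half the (few) edges train, the rest are test positives against 5000
    sampled negatives.
    """
    rocs: dict[str, list[float]] = {}
    for k in seeds:
        gog, _ = gen_gog(SyntheticSpec(seed=300 + k, **SPARSE_SPEC))
        n_edges = len(gog.external_edges())
        n_train_pos = n_edges // 2
        split = make_split(
            gog, n_train_pos, n_train_pos,
            {"n_test_pos": n_edges - n_train_pos, "n_test_neg": 5000},
            seed=400 + k,
        )
        for name, kw in (("fingerprint", FINGERPRINT_KW), ("embedding_only", EMBEDDING_KW)):
            est = DualGraphConv(random_state=500 + k, **kw)
            rocs.setdefault(name, []).append(evaluate_on_split(est, gog, split).roc_auc)
            if progress:
                progress(f"sparse seed {k} {name}: {rocs[name][-1]:.3f}")
        katz = SimilarityIndexPredictor("katz")
        rocs.setdefault("katz", []).append(evaluate_on_split(katz, gog, split).roc_auc)
        if progress:
            progress(f"sparse seed {k} katz: {rocs['katz'][-1]:.3f}")
    return {name: _mean(v) for name, v in rocs.items()}


def null_benchmark(seed=901, progress=None) -> dict[str, float]:
    """No-signal regime: every method's test ROC-AUC, plus the chance band.

    Returns per-method ROC and ``three_se``, three null standard errors of
    the ROC estimate (Hanley–McNeil) for the test set size.
    """
    gog, _ = gen_gog(SyntheticSpec(seed=seed, **NULL_SPEC))
    n_test_pos, n_test_neg = 150, 1350
    split = make_split(
        gog, 150, 150, {"n_test_pos": n_test_pos, "n_test_neg": n_test_neg},
        seed=seed + 1,
    )
    out: dict[str, float] = {}
    for name, kw in (
        ("dual", DUAL_KW),
        ("internal_only", INTERNAL_KW),
        ("embedding_only", EMBEDDING_KW),
        ("fingerprint", FINGERPRINT_KW),
    ):
        est = DualGraphConv(random_state=seed + 2, **kw)
        out[name] = evaluate_on_split(est, gog, split).roc_auc
        if progress:
            progress(f"null {name}: {out[name]:.3f}")
    for idx in ("katz", "common_neighbors", "jaccard"):
        out[idx] = evaluate_on_split(SimilarityIndexPredictor(idx), gog, split).roc_auc
        if progress:
            progress(f"null {idx}: {out[idx]:.3f}")
    out["three_se"] = 3 * float(
        np.sqrt((n_test_pos + n_test_neg + 1) / (12.0 * n_test_pos * n_test_neg))
    )
    return out


def memorization_fixture(seed=0):
    """10 distinct-size molecules, 4 positive + 4 negative training pairs.

    A well-posed memorization target: distinct molecule sizes guarantee
    distinguishable compound representations.
    """
    from .synthetic import NOMINAL_VALENCE  # noqa: F401  (alphabet shared)
    from .gog import AtomSignature, InternalGraph

    rng = np.random.default_rng(seed)
    mols = []
    for i in range(10):
        n = 3 + i
        elements = [str(rng.choice(["C", "N", "O", "S"])) for _ in range(n)]
        adj: list[list[int]] = [[] for _ in range(n)]
        for k in range(1, n):
            options = [m for m in range(k) if len(adj[m]) < 4]
            m = int(rng.choice(options))
            adj[k].append(m)
            adj[m].append(k)
        adj = [sorted(a) for a in adj]
        atoms = []
        for k in range(n):
            val = NOMINAL_VALENCE.get(elements[k], 4)
            atoms.append(
                AtomSignature(elements[k], val, max(val - len(adj[k]), 0), len(adj[k]))
            )
        mols.append(InternalGraph(graph_id=f"m{i}", atoms=atoms, adjacency=adj))
    edges = [
        (f"m{i}", f"m{j}")
        for i in range(10)
        for j in range(i + 1, 10)
        if rng.random() < 0.35
    ]
    gog = build_gog(mols, edges)
    pos = gog.external_edges()[:4]
    neg = sample_negatives(gog, 4, seed=seed)
    dataset = LinkDataset([(i, j, 1) for i, j in pos] + [(i, j, 0) for i, j in neg])
    return gog, Split(train=dataset, test=LinkDataset([], role="test"), message_edges=pos)


def memorization_benchmark(seed=0, epochs=200) -> float:
    """Final eval-mode summed cross-entropy after memorization training."""
    from .external import gog_message_adjacency
    from .predictor import cross_entropy_loss
    from .training import TrainConfig, train

    gog, split = memorization_fixture(seed)
    cfg = TrainConfig(
        d=16, T=1, L=1, epochs=epochs, batch_size=8, seed=seed,
        validation_fraction=0.0, dropout_rate=0.0,
    )
    model, _ = train(gog, split, cfg)
    pairs, labels = split.train.arrays()
    adj = gog_message_adjacency(gog, split.message_edges)
    return cross_entropy_loss(model.predict_proba_pairs(adj, pairs), labels)


def printed_network_stats(n_compounds: int, n_edges: int, seed=0) -> dict:
    """Pair count and density of a network with the given size, via gog_stats.

    Builds a placeholder GoG (single-atom compounds, uniformly random edges)
    of exactly the requested size; the pair count and density depend only on
    the counts.
    """
    from .gog import AtomSignature, InternalGraph

    sig = AtomSignature("C", 4, 4, 0)
    mols = [
        InternalGraph(graph_id=f"m{i}", atoms=[sig], adjacency=[[]])
        for i in range(n_compounds)
    ]
    rng = np.random.default_rng(seed)
    total = n_compounds * (n_compounds - 1) // 2
    codes = rng.choice(total, size=n_edges, replace=False)
    starts = np.array(
        [i * (2 * n_compounds - i - 1) // 2 for i in range(n_compounds - 1)],
        dtype=np.int64,
    )
    rows = np.searchsorted(starts, codes, side="right") - 1
    cols = codes - starts[rows] + rows + 1
    gog = build_gog(mols, [(f"m{i}", f"m{j}") for i, j in zip(rows, cols)])
    s = gog_stats(gog)
    return {"n_pairs": s.n_pairs, "density": s.density, "n_edges": s.n_edges}
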