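# Methods

This note records the modeling assumptions, the numerical choices, and the
design decisions behind `gognn`, in the spirit of a model-documentation page:
what the code computes, why the defaults are what they are, and what the
synthetic benchmarks do and do not demonstrate.

## Model

**Graph of graphs.** A GoG is a two-level undirected structure: compounds as
external nodes, each carrying an internal molecular graph. Internal graphs
are atom-labeled and bond-typed-free: bond orders, charges, stereochemistry
and explicit hydrogens are out of scope; hydrogen counts enter only through
the atom signature. Atom identity is the signature tuple (element, valence,
hydrogen count, degree, aromatic flag), which keys a trainable embedding
table — two atoms with equal signatures share one embedding row.

**Internal convolution.** T neighborhood-aggregation steps with weight
matrices selected by the *receiving* atom's degree. Degrees are bucketed:
degree 0 has its own bucket, degrees 1–5 their own, degrees above 5 share
the top bucket (organic valence rarely exceeds 5; the cap bounds parameter
count). Whether the neighbor-side matrix M should instead be selected by
the *sending* atom's degree is ambiguous in the underlying formulation;
receiver-degree is implemented for both terms, which keeps the operation a
single gather-matmul. The compound vector sums a per-atom softmax of the
accumulated states over steps t = 0…T (T+1 terms, including the raw
embedding), so Σ_dim g = |atoms| exactly — a useful invariant that the test
suite checks to float tolerance.

**External convolution.** L steps over the inter-compound network, one
(U, V) pair per step, no degree conditioning (external degrees are large
and varied). Both the intermediate activation f and the final pooling σ
default to row-wise softmax, matching the reference formulation literally;
ReLU is selectable for ablation. The message adjacency is an explicit
argument and during training contains *fit-split training positives only*:
neither test links nor validation positives are visible to message passing.
Validation positives were originally left in the message graph; that
inflates validation ROC-AUC (the model can read the link off the graph) and
makes best-on-validation selection favor exactly the wrong models, so they
are excluded.

**Link predictor.** Symmetric featurization (h_i + h_j) ⊕ (h_i ⊙ h_j),
then a ReLU MLP with hidden sizes 128 and 64 and a 2-way softmax output.
Dropout 0.2 after each hidden ReLU in train mode. Convolution layers are
bias-free (the update equations carry no bias); the MLP head has biases, as
is standard. Symmetry p(i,j) = p(j,i) is exact — the two orders produce the
identical computation graph — and asserted bit-for-bit in tests.

**Loss and optimization.** Summed (not averaged) cross-entropy over labeled
pairs; mini-batches use the batch sum, so the learning rate acts on the sum
scale. Adam with lr 0.001, β = (0.9, 0.999), ε = 1e-8. Every trainable
tensor — atom table, W/M, U/V, MLP — updates end-to-end. Training history
records the per-epoch summed loss and, when a validation fraction (default
10 % of training pairs) is set, validation ROC-AUC; the best-validation
epoch's parameters are returned. A non-finite loss aborts with an error
rather than continuing silently.

## Numerical core

No deep-learning framework is used: `gognn.autodiff` is a ~200-line
reverse-mode autodiff over float64 NumPy arrays with exactly the operations
the model needs (matmul, degree-bucketed linear maps, gather/segment-sum
for graph aggregation, ReLU, row-wise softmax, dropout, fused softmax
cross-entropy). Float64 everywhere makes finite-difference gradient checks
meaningful: the suite verifies backpropagated gradients against central
differences at 1e-4 relative error per layer and 1e-3 end-to-end.

**Initialization.** Atom embeddings: N(0, 0.1²) per component, one draw per
distinct signature (the scale is a free choice; 0.1 keeps initial pooled
vectors in the softmax's responsive range). A dedicated fallback row covers
signatures unseen at table construction (first use logged). Internal conv
weights: N(0, 1). Because every compound vector is a softmax output,
components are O(1/d); unit-scale weights keep internal pre-activations
O(1), and smaller scales demonstrably stall optimization for dozens of
epochs. External conv weights: N(0, 0.1²) — an order of magnitude smaller,
because external pre-activations sum over node degrees that reach hundreds
in heavy-tailed networks, and a large initial V saturates the softmax,
erasing the degree gradations the model needs to rank hub pairs. MLP head:
He initialization (std √(2/fan_in)), the standard choice for ReLU layers,
which matters at the 4096-wide fingerprint input. Softmax temperature is
fixed at 1 throughout. Cross-entropy on explicit probabilities clamps
p = 0 at 1e-12 with a warning; the training path uses the fused
log-sum-exp form and needs no clamp.

## Data handling

Compound indexing is 0-based internally; files use string ids mapped at
load. Molecules over the 64-atom cap are filtered at load time with a
logged skip count. Negative examples are uniformly sampled unconnected
pairs (distinct, outside an exclusion set, reproducible by seed); for pair
spaces above 2 million the sampler switches from exhaustive enumeration to
rejection sampling. Test sets either take explicit positive/negative counts
or preserve the network's imbalance (positive fraction = link density).
Train and test pair sets are disjoint; message edges are training positives
only.

## Synthetic benchmark: what it emulates

Real chemical networks vary along two axes the generator reproduces —
link density and degree-tail weight — and links correlate with both
molecular substructure and network community. The planted-factor model:
every compound is a random connected degree-≤4 molecule over {C, N, O, S};
a fraction carries a planted aromatic N–O–S triangle (provably absent
otherwise — candidate bonds completing such a triangle are rejected in
non-motif molecules); compounds belong to communities (within/between rate
ratio p_in : p_out); pairs where both carry the motif get their link
probability multiplied by `motif_boost`; the `powerlaw` degree model
additionally multiplies pair propensities by Chung–Lu-style weights drawn
from a discrete power law (inverse-CDF, truncated at n−1). Propensities are
rescaled to hit the target density in expectation; because probabilities
are capped at 1, the scale is solved by bisection rather than linearly,
otherwise heavy-tailed regimes undershoot their target density.

What it does **not** emulate: chemically realistic molecules (random trees
plus a few extra edges, no rings beyond chance and the planted triangle),
realistic substructure-link mechanisms (one motif, multiplicative effect),
or degree sequences of any particular real network. Passing benchmarks
therefore demonstrates that each method recovers the kind of signal it is
built for — not performance on any real chemical network.

## Frozen study conditions (`gognn.benchmarks`)

- **Dense, heavy-tailed** (drug-interaction-like): n = 300, target density
  0.09, power-law tail γ = 2.2, motif boost 5, p_in/p_out = 4; 1000
  training positives + 1000 negatives, imbalance-preserving 2000-pair test;
  3 seeds. Models: dual (d = 32, T = 1, L = 5, batch 128, 30 epochs),
  internal-only (same but no external conv), Katz (β = 0.001, scored on the
  training-positive adjacency — scoring with test edges present would be
  leakage). L = 5 from the {1, 3, 5} grid: external depth is what matters
  in dense networks, and it was selected on held-out validation.
  Expected: dual clearly above both ablations.
- **Extremely sparse** (metabolite-like): n = 600, bernoulli links at mean
  external degree 1.70 — the degree implied by 5041 edges over 5920
  compounds. Density itself is not scale-free (density = mean degree /
  (n − 1)), so a scaled-down sparse network preserves the *degree*, not the
  raw density; carrying the raw density to n = 600 would leave ~54 edges,
  too few to form a train/test protocol at all. Half the edges train
  (≈ 240), the rest are test positives against 5000 sampled negatives;
  fingerprint and embedding modes train 100 epochs (tiny data, cheap
  epochs). Expected: path- and embedding-based methods near chance, frozen
  fingerprints best — by a modest margin, since ≈ 240 training pairs
  support only weak generalization (a ridge-regularized linear probe on the
  same features reaches ≈ 0.58 mean ROC-AUC, so ≈ 0.55 from the MLP head is
  near the practical ceiling, against a motif-flag oracle of ≈ 0.68).
- **Null**: n = 300, density 0.05, no motif effect, uniform community
  rates. Only 150 of ≈ 2250 edges are used for training: sampling training
  positives *without replacement* depletes the remaining (test) edges of
  heavily-used compounds, anti-correlating test links with memorized
  per-compound linkiness; a small training fraction keeps this
  transductive-split artifact inside the chance band. Every method must
  land within three null standard errors (Hanley–McNeil) of ROC-AUC 0.5.

The memorization check trains the dual model (d = 16, T = L = 1, full-batch,
dropout off — a capacity check deliberately removes the regularizer that
exists to prevent memorization) on a fixed 10-compound, 8-pair fixture for
200 epochs; molecules have pairwise distinct sizes so their representations
are guaranteed distinguishable, making memorization well-posed. Final
summed eval-mode loss must fall below 0.05.

## Interface conventions

Trainable models follow the scikit-learn estimator pattern
(hyperparameters in `__init__`, `get_params`/`set_params`, fitted state in
trailing-underscore attributes). Because every pair is scored in the
context of the whole GoG, `fit` takes `(gog, pairs, labels)` rather than a
plain feature matrix — the GoG is the dataset, pairs are the samples. The
similarity indices expose the same surface so evaluation code is
method-agnostic. The CLI (`gognn simulate|train|predict|evaluate|baseline|stats`)
is a thin wrapper over these estimators; every run logs seed, config hash
and versions.

## Known limitations

- Double-softmax external convolution saturates on hubs; degree information
  survives only in simplex direction, which is why the dual model needs the
  small-scale V initialization to compete with path-counting indices on
  degree-driven networks.
- The relational-embedding mode is transductive: compounds unseen in
  training keep near-random embeddings.
- Katz via sparse LU on queried columns is exact but dense-per-column;
  fine at benchmark sizes, not engineered for very large n.
- Mini-batch training recomputes the full-graph forward pass per batch —
  simple and correct at desk scale, wasteful for large GoGs (neighborhood
  sampling is deliberately out of scope).
- Evaluation is a single train/test split per seed; no confidence intervals
  or paired tests are provided.
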