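# Methods

This note documents the models and procedures implemented in `multidda`,
the assumptions behind them, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## Problem setting

Drug repurposing asks which approved drugs might treat which diseases.
Given |C| drugs, |D| diseases, a sparse binary matrix A_known ∈ {0,1}^{|C|×|D|}
of known drug–disease associations, five binary drug descriptor matrices
(targets, enzymes, pathways, chemical substructures, and drug–drug
interaction profiles), and a MeSH-style disease ontology DAG, the task is
to score every unobserved (drug, disease) pair. It is a transductive link
prediction problem on a heterogeneous graph under severe class imbalance:
known positives are a few percent of all pairs, so average precision
(AUPR) is the primary metric and ROC AUC is reported alongside.

Every pair not listed as a known association is treated as a hard negative
— in the loss and in evaluation. This is the standard closed-world
assumption for this benchmark family; it understates performance insofar
as some "negatives" are simply undiscovered positives.

## Similarities

**Drugs.** Each drug's binary modality vectors are concatenated and pairs
are compared by the Jaccard index, S^c_ij = |x_i ∩ x_j| / |x_i ∪ x_j|.
Two all-zero vectors get similarity 0 (no evidence of similarity, and no
0/0). All five modalities enter the concatenation by default; the subset
is configurable. The matrix is kept dense and unthresholded.

**Diseases.** The MeSH disease branch is a rooted DAG whose edges point
from broader to narrower terms. A disease d assigns each node n in its
ancestor closure N(d) a contribution

    C_d(d) = 1,   C_d(n) = Δ · max { C_d(n′) : n′ a child of n on a path to d },

a Wang-style recursion in which Δ ∈ (0,1) discounts each step away from
the disease. The similarity of two diseases is the mass of their shared
ancestry relative to their total semantic values:

    S^d_ij = Σ_{n ∈ N(i)∩N(j)} (C_i(n) + C_j(n)) / (DV(i) + DV(j)),
    DV(d) = Σ_{n ∈ N(d)} C_d(n).

The diagonal is exactly 1 and all entries lie in [0,1]. Δ defaults to 0.5,
the convention in the DAG semantic-similarity literature; the value is
exposed in the configuration. Note that S^d_ij is *not* globally monotone
in Δ: when one disease's closure is much deeper than the shared ancestry,
raising Δ inflates its own semantic value faster than the shared
numerator (e.g. one disease mapped at the root and the other at depth m
gives S = (1+Δ^m)/(2+Σ_{t≤m}Δ^t), which decreases in Δ). Monotonicity
does hold for same-depth diseases in a tree, and the test suite asserts
exactly that.

## Heterogeneous graph

Drugs and diseases form one node set (drugs first, 0-based). The block
adjacency and initial features are

    A  = [[S^c, A_known], [A_knownᵀ, S^d]],
    H0 = [[0,   A_known], [A_knownᵀ, 0  ]],

so the first convolution sees pure association topology. Propagation uses
the symmetric GCN renormalization Â = D̃^{-1/2}(A+I)D̃^{-1/2} with
self-loops — the field-standard choice, which also keeps the unit
similarity diagonal meaningful. During cross-validation the held-out
fold's positives are zeroed in **both** A and H0 before training (both
encode A_known; leaving either would leak test labels), and excluded from
the training loss. The leakage audit in the acceptance script counts
test-fold entries in every fold's training structures; the count must be 0.

## Model

Per level l = 0..L-1 (L = 3 by default):

1. **Graph convolution** H ← ReLU(Â H W^l). Level 0 maps the n-dimensional
   H0 rows to the embedding dimension; later levels absorb the
   context-widened input back down, so widths stay bounded.
2. **Modality branches** project each selected binary matrix X_k through
   its own affine layer with ReLU, O_k = ReLU(X_k P_k^l + b_k^l) — one
   branch per modality per level, so each modality can adapt separately
   to the shared latent space.
3. **Fusion** combines branch outputs. Default is a softmax-weighted sum
   with learnable mixing logits (the model learns each modality's
   importance); horizontal concatenation is selectable via
   `fusion="concat"`.
4. **Context injection** appends the fused drug context to drug rows,
   h_i ← [h_i ∥ o_i]; disease rows are zero-padded to the same width so
   the next convolution sees uniform dimensionality.

After the last level, **multi-head graph attention** reweighs neighbors
(neighborhoods are the nonzero entries of the un-normalized A; an
isolated node falls back to a self-loop):

    α^k_ij = softmax_{j∈N_i} LeakyReLU(a_kᵀ [W_g^k h_i ∥ W_g^k h_j]),
    h_i′ = ELU((1/K) Σ_k Σ_{j∈N_i} α^k_ij W_g^k h_j),

with K = 4 heads and LeakyReLU slope 0.2. Finally a 2-layer MLP scores
each pair from the concatenated embeddings, sigmoid(MLP([h_i ∥ h_j])),
with hidden width equal to the embedding dimension.

**Loss and optimization.** Weighted binary cross-entropy over the full
score matrix, positive-class weight = #negatives/#positives by default,
optimized full-batch with Adam with decoupled weight decay (default
5e-3). The decay matters here: with full-matrix supervision on a small
transductive graph, high-dimensional binary inputs — informative or not —
can act as per-drug identifiers, and unregularized training memorizes
them (train AUC far above held-out AUC). Weight decay suppresses that
memorization and roughly doubles the held-out advantage of genuinely
informative features over noise features in the ablation experiment. The
training path computes the loss from logits via softplus identities for
numerical stability; the public `weighted_bce_loss` operates on scores
and is verified to agree. All tensors are float64; all randomness
(initialization, dropout, folds, subsampling) flows from a single
configured seed, making every run bit-reproducible.

**Defaults** (and why): embedding dimension 64 and learning rate 0.005
from the standard search grid ({64,128,256} × {1e-4…1e-2}) — the smallest
dimension and mid-grid rate, adequate at desk scale; 3 levels (the
hierarchical-injection depth); dropout 0.1 on embeddings during training;
Xavier-uniform initialization; 500 iterations by default with 10 000
available via configuration for benchmark-scale runs. The implementation
is pure numpy with a small reverse-mode autodiff engine
(`multidda/autodiff.py`); at a few hundred nodes, full-batch dense linear
algebra is faster than any minibatched alternative, and gradients are
validated against finite differences.

## Evaluation protocol

Known positives are randomly partitioned into five near-equal folds; each
serves once as the test set. Scores are evaluated on held-out positives
against the full negative universe. AUC is the rank statistic (ties count
½); AUPR is step-wise average precision (not trapezoidal PR
interpolation, which is optimistic). Thresholded metrics — recall,
specificity, accuracy, precision, F1 — use the per-fold F1-maximizing
threshold by default (the threshold is reported), with a fixed-threshold
override; the package reports mean ± sd over folds. A paired t-test
utility compares fold metrics of two model variants.

The ablation experiment restricts the *branch* inputs to a single
modality; the graph (similarities, associations) is unchanged, matching
the intent of isolating each descriptor's contribution to the drug node
updates. The fraction experiment holds out a fixed test set (20% of
positives), then trains on nested subsamples (80%…100%) of the remaining
positives — nesting removes subsample-composition noise from the
comparison. Dropped positives become unknowns (zeros), exactly like any
unobserved pair.

## Synthetic benchmark

The generator plants a recoverable low-rank structure:

* latent factors U ∈ R^{|C|×r}, V ∈ R^{|D|×r}, standard normal, r = 4;
* association probabilities sigmoid(s·⟨u_i,v_j⟩/√r + offset), with the
  offset found by bisection so the realized density hits its target
  (0.05 by default); A_known is a Bernoulli draw;
* each modality feature is a thresholded noisy linear readout of U:
  z = β·standardize(Uw) + √(1−β²)·ε, cut at the 85th percentile
  (≈15%-dense binary fingerprints). The per-modality informativeness
  β ∈ [0,1] dials signal-to-noise; β = 0 yields pure Bernoulli noise
  carrying nothing about U (verified by a null-correlation test);
* the DAG is a random bounded-depth tree plus ~10% forward cross-edges
  (acyclic by construction); diseases are attached to non-root nodes in
  DFS order after sorting by their leading principal direction in V, so
  V-proximity translates into shared ancestry and S^d carries disease-side
  signal.

The latent scale s = 3.5 was set by a power analysis of the generator
alone: scoring pairs with the *true* generating probabilities (the Bayes
ceiling) should reach AUC ≈ 0.95 at the default density, so recovery
experiments measure the method rather than intrinsic Bernoulli noise
(measured ceilings: s = 1.5 → 0.82, 2.5 → 0.93, 3.5 → 0.96, 5.0 → 0.99).

The default spec mirrors the real benchmark at roughly quarter scale — 67
drugs × 150 diseases, modality dimensions 62/156/116/220/522
(enzyme/target/pathway/substructure/DDI), density 5%, informativeness 0.8
— so a full training run takes well under a minute on one CPU.

**What the benchmark does not emulate:** real chemistry (substructure
vectors are not fingerprints of real molecules), the long-tailed degree
distributions of curated association databases, correlated noise between
modalities, multi-descriptor diseases, or annotation biases. Passing the
recovery experiments shows the pipeline can extract planted low-rank
structure through the full graph/branch/attention path — not that it
reproduces any particular benchmark's published numbers.

## Experiment problem sizes

The repository's tests and the acceptance script run, per seed:
structure recovery at the full default spec (67×150, 500 iterations,
3 seeds, one five-fold rotation per seed); the ablation direction at the
default spec with informativeness concentrated on the substructure
modality (β = 0.9, others 0, 4 variants × 5 seeds); and the fraction
experiment on a 40×80 bundle (300 iterations, 5 seeds). These sizes keep
a complete run in the tens of minutes on a single CPU while leaving each
effect measurable above seed noise.

## Known limitations

* Transductive only: drugs and diseases unseen at training time have no
  embedding; cold-start prediction is out of scope.
* In the transductive full-matrix setting, uninformative (noise) drug
  features still act as drug identifiers, so single-modality ablation
  differences reflect *generalization* advantages of informative features
  (partial pooling across similar drugs), which are real but much smaller
  than the overall recovery signal.
* The closed-world negative assumption biases all absolute metrics
  downward.
* Full dense matrices throughout: memory scales as O((|C|+|D|)²), fine to
  a few thousand nodes, not beyond.
* One DAG node per disease; multi-descriptor diseases are not modeled.
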