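# Methods

This note documents the model implemented by `muscle_mda`, the choices made
where the design was genuinely open, what the synthetic benchmark does and
does not demonstrate, and the package's numerical conventions.

## Problem

Given experimentally supported miRNA–disease associations (MDAs) and
auxiliary relations of both entity classes to drugs, mRNAs and lncRNAs, the
task is to score unobserved miRNA–disease pairs so that true but
undiscovered associations rank highly.  The model treats this as binary
classification over pairs, with negatives sampled uniformly from the
unobserved grid (a standard, if imperfect, proxy — some "negatives" are
simply undiscovered positives).

## Model

### Prior attribute features

* **Sequence (SM).**  Each miRNA sequence of length m is reduced to its
  k-mer frequency profile over the alphabet {A, C, G, U}: the m−k+1 sliding
  windows are counted and normalized to sum to one.  With the default k=3
  the profile is 64-dimensional.
* **Disease semantics (DSS1, DSS2).**  Diseases carry MeSH-style descriptor
  terms arranged in a DAG (edges run child → parent).  For a disease A,
  every term in DAG(A) (its terms plus ancestors) receives a contribution
  D_A(t): 1 for A's own terms, and Δ·max over children otherwise (Δ = 0.5
  by default, the conventional decay of Wang-style semantic similarity; the
  value is a config knob because the source method leaves it open).  DSS1
  of two diseases sums the contributions of shared terms and normalizes by
  the two semantic values DV = Σ_t D(t).  DSS2 replaces the decayed
  contribution with an information-content-like weight,
  −ln(#DAGs containing t / #diseases) (natural log; the log base only
  rescales DSS2 and is recorded in config), keeping the DV normalization.
  DSS2 can exceed 1 by construction and is clipped to [0, 1] by default
  (config switch to disable).
* **Interaction kernels (KM, KD).**  Gaussian interaction profile kernels
  over the binary association matrix G: K(i,j) = exp(−γ‖G(i)−G(j)‖²) with
  γ = γ′ / mean‖G(i)‖², γ′ = 1.  The squared-norm reading of the exponent
  is used throughout.  **G is rebuilt from the training-fold positives
  inside every cross-validation fold** — the kernels are the only feature
  derived from labels, and recomputing them per fold is what keeps test
  labels out of the training inputs.
* **Integration.**  DM concatenates SM and KM rows (width 4^k + n_m).  DD
  takes (DSS1+DSS2)/2 where both diseases carry ontology terms and falls
  back to KD elsewhere — the fallback exists for diseases without MeSH
  coverage.

### Multi-view topology features

Three heterogeneous views connect the two target classes through one
mediator class each: miRNA–drug–disease (MDD), miRNA–mRNA–disease (MMD),
miRNA–lncRNA–disease (MLD).  Nodes are laid out miRNA block / mediator
block / disease block (each sorted lexicographically — the ordering is a
determinism choice, not a modelling one).  **No view ever contains a direct
miRNA–disease edge**; the supervised signal reaches the model only through
the labels, so the graphs cannot leak test-fold associations.  Mediator–
mediator edges are not modelled (no such pair source is defined).

Each view gets its own multi-head graph attention encoder (parameters are
not shared across views; sharing is the other defensible reading, and a
config would be trivial, but separate parameters match the
one-encoder-per-graph presentation).  Node features start from a seeded
standard normal and are trainable.  Attention coefficients are

  α_ij = softmax_{j∈N(i)} LeakyReLU(aᵀ[W x_i ‖ W x_j]),  slope 0.2,

heads are concatenated and passed through an ELU (the activation is named
only generically in the source; ELU is the common choice for GAT stacks).
Self-loops are added to every adjacency so isolated nodes keep their own
transformed features instead of hitting an empty softmax.  After L layers a
linear projection sizes the output to the embedding dimension d; by default
d = (n_m + n_d)/2, mirroring the reference corpus relation between the stacked
node count (1778 = 901 miRNAs + 877 diseases) and the fusion feature
dimension (889).  The reference description can be read as either d = N/2 or
d = N; both are reachable through `gat.embed_dim`.

Architecture defaults: F = 128 input features, F′ = 64 per head, Φ = 4
heads, L = 2 layers.  A single dropout rate (default 0 in the library,
0.2 in the benchmark preset) applies to layer inputs and attention
coefficients, the regularization of the original GAT recipe.

### Multi-scale attentional fusion

The V per-view embeddings are stacked into X ∈ R^{V×N×d} (miRNA rows first,
disease rows second, identical order in every channel) and fused by channel
attention:

* local context L(X): a point-wise-convolution bottleneck
  BN(PWConv₂(ReLU(BN(PWConv₁(X))))) with V → r → V channels (r = 1); each
  output position depends only on the V channel values at that position;
* global context g(X): global average pooling per channel;
* gates σ(L(X) ⊕ g(X)), broadcast over positions, strictly inside (0, 1);
* output X′ = Σ_v X_v ⊗ gate_v.

The printed fusion formula keeps V channels while typing the output as
N×d; only a reduction over the view axis makes that shape true, so gated
channels are **summed** by default (`fusion.reduce = mean` is available).
Channel normalization uses the statistics of the full stack at every
forward pass; because the stack covers the entire transductive node set,
training and inference statistics coincide and no running averages are
kept.  Ablation alternatives are selectable: channel mean (ave),
elementwise product (dot), concatenation (cat), local-only gating (lf) and
a one-layer symmetric-normalized graph convolution followed by mean fusion
(gcn — an approximation; the referenced ablation does not specify its GCN).

### Classifier and training

A pair (m, d) is scored from the concatenation
[X′_m ‖ DM_m ‖ X′_d ‖ DD_d] (widths differ between the miRNA and disease
blocks; they are concatenated as-is).  The MLP has 4 hidden layers (the
depth found optimal in the reference evaluation), widths halving from the input, ReLU, dropout 0.3,
sigmoid output; binary cross-entropy is minimized end-to-end over GAT,
fusion and MLP parameters with Adam (lr 10⁻³ library default) for 200
epochs at full batch, seed 123.  An optional early stop monitors the
maximum change of the fused embedding between epochs (tol 10⁻⁴)
implementing the "representations no longer change" stopping notion; the
default is the fixed 200-epoch joint run.  Optional knobs: cosine lr decay,
decoupled weight decay, Polyak (EMA) weight averaging for prediction, and
a single dropout rate on the fused embedding rows.

### Evaluation

Stratified 5- or 10-fold cross-validation over the balanced pair set
(negatives sampled once per experiment before splitting; a per-fold
resampling mode exists).  Metrics: AUC via the Mann–Whitney/midrank
identity, AUPR by step integration of the precision–recall curve (both
verified against scikit-learn to 1e-10 in tests), and accuracy,
sensitivity, specificity, precision, MCC and F1 from the confusion matrix
at threshold 0.5.

## Synthetic benchmark

The generator plants a rank-8 latent factor u per entity and samples every
bipartite relation — including the labels — as
Bernoulli(sigmoid(b + signal·uᵀv)), with the intercept b calibrated by
root-finding so the realized density equals `edge_density` regardless of
signal (at signal = 0 this reduces exactly to logit(density), the null
world).  Sequences carry the signal through cluster-biased nucleotide
composition (the sign pattern of the first two latent coordinates selects
one of four base-composition profiles).  The disease ontology is a forest
with one ancestor chain per latent dimension ending in two sign-keyed
descriptor terms; a disease's term set picks the descriptor matching each
latent sign, so shared terms grow with latent agreement and semantic
similarity is informative by construction.

Defaults: 150 miRNAs, 120 diseases, 100 drugs, 200 mRNAs, 150 lncRNAs,
rank 8, signal 3, edge density 5 % (between the ~1.6 % density of the real
association database and the minimum needed for stable folds at desk
scale), sequence lengths 19–25 nt, DAG depth 4.

What the benchmark emulates: low-rank association structure shared across
views, attribute channels correlated with that structure, class-balanced
evaluation.  What it does not: hub/degree skew of curated databases,
literature bias, miRNA family structure, real MeSH topology, and the
scale of the real corpora.  Passing it therefore shows the pipeline
recovers plantable signal end-to-end without leakage — not that it would
match reported performance on the real corpora, which require external
downloads that are out of scope here.

### Benchmark training preset

`benchmark_train_config()` is the configuration used by the acceptance
tests and script: the default architecture with lr 5·10⁻³, GAT dropout
0.2 and fused-embedding dropout 0.3.  The higher learning rate and the two
dropout rates are there because the desk-scale benchmark trains full-batch
from scratch on ~1 700 pairs, where the library defaults (tuned for
nothing in particular) under-train and over-memorize respectively.  Fold
sizes, entity counts and generator parameters are the study conditions and
are never adjusted per run.

## Numerical choices

* float64 throughout; the autodiff engine is a minimal reverse-mode
  implementation over numpy (matmul, broadcasting arithmetic, reductions,
  gathers, the activations) with gradients verified against central finite
  differences.  A fused masked-softmax op implements attention rows in one
  node so dense (n×n) graphs stay memory-bounded.
* Attention softmax subtracts the per-row neighborhood maximum before
  exponentiation; isolated rows (impossible after self-loops) would yield
  all-zero coefficient rows rather than NaN.
* BCE is computed from logits in the max/log1p-exp form.
* Similarity matrices are validated symmetric to 1e-10; DSS1/KM/KD carry
  unit diagonals by construction (DSS2's diagonal is not 1 in general).
* Matrix serialization is headered TSV at %.17g, which round-trips float64
  bit-exactly (`read_csv` uses round-trip float parsing).
* Ties in AUC are handled by midranks; AUPR uses last-of-tie-group
  evaluation points, matching the reference step integration.

## Known limitations

* Dense adjacency and attention: fine to a few thousand nodes per view,
  not beyond; sparse attention would be the next step at real-data scale.
* The transductive design (embeddings for a fixed node set) cannot score
  entities absent from every view and the label set; attribute features
  mitigate but do not remove the cold-start gap.
* The `gcn` fusion ablation is an approximation (single symmetric-
  normalized propagation, shared linear map, mean fusion).
* Negative sampling treats unobserved pairs as negatives; reported
  specificity/precision inherit that assumption.
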