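# muscle-mda

Multi-view graph attention prediction of miRNA–disease associations.

miRNAs regulate gene expression post-transcriptionally, and their
dysregulation is implicated in many diseases; experimentally confirming
individual miRNA–disease associations (MDAs) is slow, so computational
ranking of candidate pairs is used to prioritize experiments.  This package
implements a multi-view, multi-scale attentional pipeline for that task,
aimed at computational biologists who want a tested, self-contained
implementation: every stage runs on plain-text inputs (FASTA, two-column
TSV edge lists, a flattened ontology) or on the built-in synthetic
benchmark — no database downloads required.

## The model

Pairs (m, d) are classified from two complementary representations:

**Prior attribute features.**  Sequence 3-mer frequency profiles
SM ∈ R^{n_m×64}; two Wang-style disease semantic similarities over the
MeSH-like descriptor DAG, from decayed contributions
D_A(t) = max{Δ·D_A(t′)} (DSS1) and information-content weights
−ln(#DAGs ∋ t / n_d) (DSS2); and Gaussian interaction-profile kernels
K(i,j) = exp(−γ‖G(i)−G(j)‖²), γ = γ′/mean‖G‖², rebuilt from
**training-fold positives only** inside every CV fold.  These integrate to
DM = SM ⊕ KM and DD = (DSS1+DSS2)/2 with KD fallback for diseases without
ontology terms.

**Multi-view topology features.**  Three heterogeneous graphs couple
miRNAs and diseases through mediator molecules — drugs (MDD), mRNAs (MMD),
lncRNAs (MLD) — with all direct miRNA–disease edges excluded so the graphs
cannot leak labels.  Each view is encoded by its own multi-head graph
attention network,
α_ij = softmax_j LeakyReLU(aᵀ[Wx_i ‖ Wx_j]),
x′_i = ‖_φ σ(Σ_j α^φ_ij W^φ x_j),
and the per-view embeddings X ∈ R^{V×N×d} (N = n_m + n_d stacked rows) are
fused by multi-scale channel attention: a point-wise-convolution bottleneck
local context plus a global-average-pooled context gate each channel
through a sigmoid, X′ = Σ_v X_v ⊗ σ(L(X) ⊕ g(X))_v.

An MLP on [X′_m ‖ DM_m ‖ X′_d ‖ DD_d] is trained end-to-end with the GAT
and fusion parameters by Adam on binary cross-entropy; evaluation is
stratified 5/10-fold cross-validation with AUC, AUPR, accuracy,
sensitivity, specificity, precision, MCC and F1.  Ablation switches cover
feature subsets, alternative fusion strategies (mean, product,
concatenation, local-only, GCN) and a single-heterogeneous-graph mode.

Because the neural stack is small, it runs on a compact reverse-mode
autodiff engine over numpy (`muscle_mda.autodiff`) — no deep-learning
framework needed; gradients are finite-difference-verified in the tests.

## Worked example

Generate a synthetic world with planted rank-8 signal and cross-validate
the full pipeline:

```python
from muscle_mda import SyntheticConfig, generate_world, run_cv
from muscle_mda.synthetic import benchmark_train_config

config = SyntheticConfig(n_mirna=60, n_disease=48, n_drug=30, n_mrna=50,
                         n_lncrna=40, edge_density=0.08, seed=11)
world = generate_world(config)
print(f"{len(world.positives)} planted associations "
      f"({len(world.mirnas)} miRNAs x {len(world.diseases)} diseases)")
results = run_cv(world.model_inputs(), world.dataset(folds=5),
                 benchmark_train_config(seed=11))
print(results.summary())
```

prints (about two minutes on one CPU):

```
236 planted associations (60 miRNAs x 48 diseases)
Fold     Auc              Aupr             Accuracy         Sensitivity      Specificity      Precision        Mcc              F1
1        0.6551           0.6338           0.6000           0.6042           0.5957           0.6042           0.1999           0.6042
2        0.7779           0.7543           0.7053           0.7021           0.7083           0.7021           0.4105           0.7021
3        0.7759           0.7874           0.6702           0.6383           0.7021           0.6818           0.3411           0.6593
4        0.8212           0.7879           0.7979           0.8085           0.7872           0.7917           0.5959           0.8000
5        0.7202           0.6898           0.6596           0.7234           0.5957           0.6415           0.3218           0.6800
Average  0.7501+/-0.0573  0.7307+/-0.0602  0.6866+/-0.0652  0.6953+/-0.0710  0.6778+/-0.0734  0.6843+/-0.0634  0.3738+/-0.1301  0.6891+/-0.0643
```

Each row is one held-out fold of the balanced pair set (positives plus an
equal number of sampled non-associations); the average AUC of 0.75 at this
deliberately small scale says the model recovers a substantial part of the
planted low-rank structure from the graphs and attributes alone — the
default benchmark scale (150×120 entities) reaches mean AUC ≈ 0.86, and
chance level is 0.5 (verified by the signal-free null world).  At the
default scale attribute-only ablations score distinctly lower than the
full multi-view model, mirroring the motivation for the multi-view design.

The same pipeline is scriptable from the shell:

```sh
muscle-mda simulate --out fixtures           # write synthetic text inputs
muscle-mda cv --config run.yaml              # cross-validate, emit TSV
muscle-mda predict --config run.yaml --top 50  # ranked candidates per disease
```

with a YAML config naming the input paths and any hyperparameter
overrides; every run writes a JSON manifest (resolved config, hash, seed)
from which it can be reproduced.  See `docs/methods.md` for the model
details, defaults and limitations.

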