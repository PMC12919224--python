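# Methods

This note records the modeling assumptions, parameter choices and
numerical decisions behind `treefuse`, and what the synthetic benchmarks
do and do not demonstrate.

## Model and assumptions

The classifier assumes three sample-aligned real feature matrices
(typically scaled to [0,1]) and a multiclass label vector. Its central
premise is that a supervised tree ensemble is a useful probe of
task-specific feature structure: if feature *a* is split on before
feature *b* along a root-to-leaf path, then *a* stratifies samples into
subgroups within which *b* refines the decision. The directed weighted
graph aggregating these precedence pairs across trees is a
task-conditioned dependency structure — emphatically not a causal or
regulatory network — and doubles as supervised feature selection, since
only split-upon features become nodes.

The graph enters the network once, as a Hadamard mask on the first
layer. This keeps the architecture sparse in exactly the places the
trees found uninformative and bounds the first layer's effective
parameter count by the edge count plus `p*` self-loops. There is no
multi-hop message passing: one masked layer, then dense.

Tensor fusion assumes cross-modality interactions are multiplicative.
Augmenting each embedding with a constant 1 makes the rank-3 outer
product contain every lower-order term, so the model does not have to
choose between unimodal, bimodal and trimodal signals; the CP
parameterization makes this affordable and is trained end to end — no
tensor is ever formed and no ALS-style decomposition of a formed tensor
is performed (exact tensor rank determination is NP-hard; the rank R is
an ordinary hyperparameter).

## Ordered-pair semantics for graph construction

"*a* appears before *b*" is read as precedence, not parent-child
adjacency: all ordered pairs of distinct features along a path
contribute. A pair is counted once per path regardless of repeated
occurrences, and by default once per *tree* (a tree containing the pair
on several paths adds weight 1); per-path counting is available via
`count_mode="per-path"`. Repeated features along one path can create
2-cycles — these are kept. Self-pairs are never stored; self-connectivity
enters only through `Ã = A + I` with weight exactly 1. A multiclass
boosted ensemble grows one tree per class per round, so an M-round
ensemble contributes up to M·C trees to the counts.

The directed normalization `D̃^{-1/2} Ã D̃^{-1/2}` uses the same
row-sum degree on both sides even though `Ã` is asymmetric — the formula
as specified; it keeps high-degree features from dominating while
preserving directionality (`N` is generally asymmetric). The undirected
ablation symmetrizes with `A + Aᵀ` (weight-mass preserving; `max(A,Aᵀ)`
is available), which is deliberately not idempotent.

## Network and training choices

Tunable parameters (defaults = the selected operating point): trees
M = 100; hidden width 64; one dense layer per branch; Adam lr 1e-4;
batch 64; max 1000 epochs; dropout 0.5; L2 λ = 0.01; early-stopping
patience 10 with min-delta 1e-3 on validation loss; CP rank R = 48;
3 residual blocks.

Decisions the source material left open, resolved as follows:

- **Branch output width.** The notation suggests the masked layer's
  `p*`-wide output feeds fusion directly, while the experimental setup
  uses width-64 hidden layers. Default: a width-64 dense layer after the
  masked layer (computationally coherent with R = 48);
  `notation_faithful_width=True` switches to `Z_i = H₁` (width `p*`).
- **Initialization.** All dense/projection weights use symmetric uniform
  Glorot scaling. The masked first layer uses *support-aware* scaling:
  the effective weight is `W ⊙ N`, so a unit's true fan-in is its graph
  degree, and each connection is further damped by its normalization
  entry; raw weights are therefore drawn with a degree-based limit
  divided by the local `|N|` magnitude. Without this, the effective
  first layer starts orders of magnitude too small and the early
  optimization stalls.
- **Batch normalization** sits after the dense pre-activation, before
  ReLU. Running statistics are warm-started from one training-mode pass
  over the training split before the first optimizer step; otherwise
  the (0,1)-initialized running moments lag the true activation
  statistics for dozens of epochs and distort the validation loss that
  early stopping monitors. The warm start touches training rows only.
- **"Dynamic" L2.** Implemented as constant-λ L2 over every trainable
  weight *matrix* (masked layers, dense layers, fusion projections,
  residual and output weights); biases, batch-norm parameters and the
  CP scale vector λ_r are excluded. A per-epoch schedule hook
  (`run_split(..., l2_schedule=...)`) allows time-varying strength; the
  default schedule is constant.
- **Early stopping** restores the best-validation-loss weights
  (checkpointed), so test metrics always correspond to the selected
  epoch. λ_r is initialized to 1 (algebraically absorbable into P₁ but
  kept explicit).
- **Zero-denominator F1 convention:** a class never predicted or never
  present contributes F1 = 0. Confidence intervals use the t quantile
  (n = 20 seeds is small); Welch degrees of freedom follow
  Welch–Satterthwaite.
- **Probability clipping** at 1e-12 inside the cross-entropy log.
- **Importance scores** use |W| rather than raw signed weights so that
  per-modality totals are nonnegative and RIO lands in [0,1]
  (`absolute=False` gives the raw sums). Cross-modality pooling of
  feature scores is only meaningful when modalities share a feature
  namespace; per-modality tables are the default and a pooled table is
  available.
- **Ties** in feature ranking break by feature name for determinism.

The training engine is a small purpose-built reverse-mode
autodifferentiation module over numpy (float64 throughout), verified
against numerical differentiation; Adam uses standard bias correction
(β = 0.9/0.999, ε = 1e-8). Determinism: one master seed per split
governs ensemble fitting, initialization, minibatch order and dropout;
identical seeds reproduce identical metrics bit for bit on one machine.

## Synthetic data: what it emulates, what it does not

The generator emulates: three modalities of strictly-interior [0,1]
values (logistic squash of Gaussian latents, per-feature random offset
and scale for heterogeneous marginals), small-n/large-p shapes, class
imbalance presets mirroring real cohorts (smallest class ≈ 5%), planted
class-informative features (additive latent shift δ before squashing,
default δ = 1.5 at noise SD 1), and an interaction-only mode where a
±1 latent per modality drives the label through the sign of their
product — each single modality is marginally uninformative there, which
specifically exercises the trimodal term of the fusion tensor.

It does **not** emulate: platform-specific marginal shapes (methylation
beta bimodality, count overdispersion), feature-feature correlation
blocks, batch effects, or missingness. Passing benchmarks therefore
demonstrates the machinery is correct and can recover planted structure
at realistic scale — not that it matches any particular real-data
performance figure.

Benchmark problem sizes were chosen to exercise the full pipeline while
keeping a complete run on one CPU in minutes: n = 300, p = 200 per
modality, 10 informative features per modality at δ = 1.5, 3–5
independent splits per condition.

## Known limitations

- Under the fixed operating point (lr 1e-4, patience 10, min-delta
  1e-3), the interaction-only benchmark sits in a long loss plateau and
  early stopping usually halts both the tensor-fusion model and the
  concatenation ablation near chance; their comparison on that benchmark
  is treated as a soft, logged expectation rather than a hard assertion.
- RIO sums importance over *all* selected features of a modality, so a
  modality whose trees scatter splits across many noise features (a
  large node set) can accumulate a large share without carrying more
  class signal. Feature-level rankings within a modality are the more
  robust interpretive output on weak-signal data.
- The fusion is trimodal by design; extending to more modalities would
  require generalizing the CP parameterization (not implemented).
- Graphs import/export as edge-list TSV; no foreign tree-model
  serializations beyond the xgboost/scikit-learn ensembles used.
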