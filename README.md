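# treefuse

Supervised multi-omics classification on **tree-derived directed weighted
feature graphs** with **low-rank tensor fusion** — a library for subtype
classification from three sample-aligned omics matrices (e.g. DNA
methylation, mRNA and miRNA expression), aimed at computational-biology
practitioners working in the small-*n*, large-*p* regime where a few
hundred patients are measured on hundreds to thousands of features per
layer.

## Method

For each modality *i* with feature matrix `X_i ∈ R^{n×p_i}` and class
labels `Y ∈ {0..C−1}^n`:

1. **Graph construction (supervised).** A boosted-tree ensemble (M = 100
   rounds) is fitted on training rows. Every root-to-leaf split path is
   read off the trees; a directed edge `a → b` records that feature `a`
   was split on before `b` somewhere along the same path, weighted by the
   number of trees containing that ordered pair. The node set `V*` (the
   `p* ≤ p` features the trees actually used) defines the reduced matrix
   `X* ∈ R^{n×p*}`.
2. **Graph-masked encoder.** With `Ã = A + I` and degree matrix `D̃`
   (row sums of `Ã`), the first hidden layer is
   `H₁ = ReLU(X* (W ⊙ D̃^{-1/2} Ã D̃^{-1/2}) + b)` — connections exist
   only along graph edges and self-loops, and high-degree features are
   damped. A dense ReLU layer (width 64, batch norm, dropout) yields the
   unimodal embedding `Z_i`.
3. **Tensor fusion, low rank.** Each `Z_i` is augmented with a constant 1
   (`Z_i* = [Z_i, 1]`), so the per-sample outer product
   `T = z₁* ⊗ z₂* ⊗ z₃*` contains all unimodal, bimodal and trimodal
   interaction terms. `T` is never materialized: the weight tensor is
   parameterized in CP form (`T ≈ Σ_r λ_r p₁ᵣ ⊗ p₂ᵣ ⊗ p₃ᵣ`), giving the
   fused embedding `h_r = λ_r (P₁z₁*)_r (P₂z₂*)_r (P₃z₃*)_r` at
   O(R·Σ(dᵢ+1)) cost (default R = 48).
4. **Residual head.** Three residual blocks
   `σ(σ(σ(X W₁) W₂) W₃ + X)` of width 64 (the first projects R → 64),
   then softmax. Training minimizes mean categorical cross-entropy plus
   `λ Σ w²` (λ = 0.01) over all weight matrices, with Adam (lr 1e-4,
   batch 64, ≤ 1000 epochs), dropout 0.5 and early stopping on validation
   loss (patience 10, min-delta 1e-3; best weights restored).
5. **Interpretability, built in.** Feature importance is read off the
   trained masked layer:
   `IF_j = Σ_u |W_ju|·1[Ã_ju≠0] + Σ_u |W_uj|·1[Ã_uj≠0]` (source +
   target connection weights); modality contributions
   `RIO_i = Σ_j IF_j^i / Σ_i Σ_j IF_j^i` sum to one.

Evaluation follows a strict leakage protocol: trees, graphs, network
weights and batch-norm statistics are fitted on the 60% training split
only; graphs stay fixed per split while the 20% validation and 20% test
rows are passed through the frozen column selection. Experiments repeat
over independent stratified splits and report mean ± SD [95% CI] with
Welch's t-tests between variants. Three single-knob ablations are
bundled: `rf` (random-forest graphs), `con` (concatenation instead of
tensor fusion) and `undir` (symmetrized adjacency).

Because matched real cohorts cannot be redistributed, the package ships
a synthetic-data generator (`treefuse.simulate`) producing three
[0,1]-scaled modalities with planted class-informative features,
realistic class imbalance presets and an optional purely trimodal
multiplicative signal.

## Worked example

```python
import treefuse as tf

dataset, truth = tf.generate(tf.SimSpec(n=300, p=(200, 200, 200),
                                        k_informative=(10, 10, 10),
                                        delta=1.5, seed=0))
split = tf.make_splits(dataset.labels, [0])[0]
result = tf.run_split(dataset, split, tf.RunConfig())
print(result.record)
```

Running `python examples/04_train_and_evaluate.py` (the same setup plus
the concatenation ablation) prints:

```
 full: accuracy=0.983 F1w=0.983 F1m=0.983 (stopped after 394 epochs)
  con: accuracy=0.983 F1w=0.983 F1m=0.983 (stopped after 229 epochs)
```

Accuracy far above the 1/3 chance level shows the planted 10-features-
per-modality signal is learned; both variants share seeds and splits, so
any gap isolates the fusion mechanism. `examples/05_interpretability.py`
prints the modality contributions and shows planted features dominating
each modality's importance ranking (e.g. 9 of the top 10 in a modality
with 15 planted features).

The `examples/` directory walks through each capability (simulation,
graph construction, the fusion oracle, training, interpretability); a
thin CLI mirrors the same steps from the shell:

```bash
treefuse simulate --out data/ --seed 0
treefuse run-all -m data/modality1.tsv -m data/modality2.tsv \
    -m data/modality3.tsv -l data/labels.tsv --seeds 20 --out results/
treefuse explain -m ... -l ... --out explain/
```

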