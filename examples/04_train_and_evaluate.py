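"""Train the full model and the concatenation ablation on one split.

Runs the end-to-end pipeline (graphs -> masked encoders -> fusion ->
residual head) with the default operating point and prints test-set
metrics for both fusion strategies.
"""

import treefuse as tf

dataset, _ = tf.generate(tf.SimSpec(n=300, p=(200, 200, 200),
                                    k_informative=(10, 10, 10),
                                    delta=1.5, seed=0))
split = tf.make_splits(dataset.labels, [0])[0]
config = tf.RunConfig()

for name in ("full", "con"):
    result = tf.run_split(dataset, split, config, tf.VARIANTS[name])
    rec = result.record
    print(f"{name:>5}: accuracy={rec.accuracy:.3f} "
          f"F1w={rec.f1_weighted:.3f} F1m={rec.f1_macro:.3f} "
          f"(stopped after {result.history['epochs_run']} epochs)")
# Both variants see identical splits and seeds; the only difference is
# tensor fusion vs concatenation of the unimodal embeddings, so the gap
# (if any) isolates the fusion mechanism. Accuracy well above the 1/3
# chance level reflects the planted 10-features-per-modality signal.
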