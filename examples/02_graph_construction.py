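"""Build a directed weighted feature graph from a boosted-tree ensemble.

Trains a small ensemble on one modality, extracts root-to-leaf split
paths, aggregates them into the directed graph (edge a->b: feature a was
split on before b in the same path), and shows the normalized adjacency
that the masked neural layer will use.
"""

import numpy as np

import treefuse as tf

dataset, truth = tf.generate(tf.SimSpec(n=200, p=(60, 60, 60),
                                        k_informative=(6, 6, 6),
                                        delta=2.0, seed=1))
split = tf.make_splits(dataset.labels, [0])[0]

X_train = dataset.matrices[0][split.train]
y_train = dataset.labels[split.train]
ensemble = tf.train_ensemble(X_train, y_train, M=30, seed=0)
paths = tf.extract_paths(ensemble)
print(f"extracted {len(paths)} root-to-leaf paths; example: {paths[0][1]}")

graph = tf.build_digraph(paths)
stats = tf.graph_stats(graph)
print(f"graph: {stats.node_count} nodes (of 60 features), "
      f"{stats.edge_count} edges, edge/node ratio {stats.edge_node_ratio:.2f}")

planted = set(truth["informative"][0].tolist())
print(f"planted features selected as nodes: "
      f"{len(planted & set(graph.nodes))} of {len(planted)}")

N = tf.normalize_adjacency(graph)
print(f"normalized adjacency: shape {N.shape}, "
      f"density {np.mean(N != 0):.3f}, max entry {N.max():.3f}")
# Nodes are the features the trees actually used (supervised feature
# reduction); the normalization D^-1/2 (A+I) D^-1/2 damps hub features
# so they cannot dominate the first network layer.
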