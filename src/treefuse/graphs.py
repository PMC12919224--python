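"""Directed weighted feature graphs from supervised tree ensembles.

A boosted (or random-forest) ensemble is trained per omics modality on
training rows only. Every root-to-leaf split path is read off the fitted
trees; a directed edge ``a -> b`` records that feature ``a`` was split on
before ``b`` somewhere along the same path, with the edge weight counting
in how many trees (default) or paths the ordered pair occurs. The nodes
of the resulting graph are exactly the features the ensemble ever split
on, and they define the reduced feature matrix used downstream.

Edges encode task-specific conditional dependence ("a stratifies samples
for which b refines the decision"), not causal regulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

__all__ = [
    "TreePath",
    "DirectedWeightedGraph",
    "GraphStats",
    "train_ensemble",
    "extract_paths",
    "build_digraph",
    "reduce_features",
    "normalize_adjacency",
    "symmetrize",
    "graph_stats",
    "write_graph",
    "read_graph",
    "to_networkx",
]

TreePath = list[int]  # split-feature ids in root -> leaf order


@dataclass
class DirectedWeightedGraph:
    """Directed weighted graph over selected feature ids.

    ``nodes`` is the ordered node list V* (sorted feature ids); ``edges``
    maps ``(source, target)`` to a positive weight. Self-pairs are never
    stored — self-connectivity enters only through the ``A + I`` step of
    :func:`normalize_adjacency`.
    """

    nodes: list[int]
    edges: dict[tuple[int, int], float]
    modality: int = 0

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValueError("self-loop stored as an edge")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge endpoint {a}->{b} outside node set")
            if w <= 0:
                raise ValueError("edge weights must be positive")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Dense weighted adjacency A with A[a, b] = weight of a -> b."""
        index = {f: i for i, f in enumerate(self.nodes)}
        A = np.zeros((self.n_nodes, self.n_nodes))
        for (a, b), w in self.edges.items():
            A[index[a], index[b]] = w
        return A


@dataclass(frozen=True)
class GraphStats:
    node_count: int
    edge_count: int

    @property
    def edge_node_ratio(self) -> float:
        return self.edge_count / self.node_count


# ---------------------------------------------------------------------------
# Ensemble training and path extraction
# ---------------------------------------------------------------------------

def train_ensemble(X: np.ndarray, y: np.ndarray, M: int = 100,
                   kind: str = "boosted", seed: int = 0):
    """Fit a supervised tree ensemble used only for graph construction.

    ``X`` must contain training-split rows ONLY; the fitted trees (and
    hence the graph) are frozen before validation/test rows are seen.
    ``M`` is the number of boosting rounds (boosted) or trees (forest);
    a multiclass boosted ensemble grows one tree per class per round.
    """
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("degenerate target: a single class cannot be modelled")
    if kind == "boosted":
        model = XGBClassifier(
            n_estimators=M, random_state=seed, n_jobs=1,
            tree_method="hist", verbosity=0,
        )
        model.fit(np.asarray(X, dtype=float), y)
    elif kind == "random-forest":
        model = RandomForestClassifier(n_estimators=M, random_state=seed, n_jobs=1)
        model.fit(np.asarray(X, dtype=float), y)
    else:
        raise ValueError("kind must be 'boosted' or 'random-forest'")
    return model


def _paths_from_json_node(node: dict, prefix: TreePath,
                          out: list[TreePath]) -> None:
    if "leaf" in node:
        out.append(list(prefix))
        return
    fid = int(str(node["split"]).lstrip("f"))
    prefix.append(fid)
    for child in node["children"]:
        _paths_from_json_node(child, prefix, out)
    prefix.pop()


def _paths_from_sklearn_tree(tree) -> list[TreePath]:
    left, right, feat = tree.children_left, tree.children_right, tree.feature
    out: list[TreePath] = []

    def walk(node: int, prefix: TreePath) -> None:
        if left[node] == -1:  # leaf
            out.append(list(prefix))
            return
        prefix.append(int(feat[node]))
        walk(left[node], prefix)
        walk(right[node], prefix)
        prefix.pop()

    walk(0, [])
    return out


def extract_paths(ensemble) -> list[tuple[int, TreePath]]:
    """Root-to-leaf split-feature paths, one per leaf per tree.

    Returns ``(tree_index, path)`` pairs; trees that never split
    contribute nothing (their single path is empty).
    """
    out: list[tuple[int, TreePath]] = []
    if isinstance(ensemble, XGBClassifier):
        dumps = ensemble.get_booster().get_dump(dump_format="json")
        for t, dump in enumerate(dumps):
            paths: list[TreePath] = []
            _paths_from_json_node(json.loads(dump), [], paths)
            out.extend((t, p) for p in paths if p)
    elif isinstance(ensemble, RandomForestClassifier):
        for t, est in enumerate(ensemble.estimators_):
            for p in _paths_from_sklearn_tree(est.tree_):
                if p:
                    out.append((t, p))
    else:
        raise TypeError(f"unsupported ensemble type {type(ensemble)!r}")
    return out


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def _ordered_pairs(path: TreePath) -> set[tuple[int, int]]:
    # all (a, b) with an occurrence of a strictly before an occurrence of b,
    # a != b; deduplicated within the path (2-cycles from repeats allowed)
    pairs: set[tuple[int, int]] = set()
    for i, a in enumerate(path):
        for b in path[i + 1:]:
            if a != b:
                pairs.add((a, b))
    return pairs


def build_digraph(paths: Iterable[tuple[int, TreePath]],
                  count_mode: str = "per-tree",
                  modality: int = 0) -> DirectedWeightedGraph:
    """Aggregate per-tree split paths into one directed weighted graph.

    ``count_mode='per-tree'`` (default) counts an ordered pair once per
    tree in which it occurs on at least one path; ``'per-path'`` counts
    once per path. Nodes are every feature appearing in any path.
    """
    if count_mode not in ("per-tree", "per-path"):
        raise ValueError("count_mode must be 'per-tree' or 'per-path'")
    nodes: set[int] = set()
    weights: dict[tuple[int, int], float] = {}
    per_tree: dict[int, set[tuple[int, int]]] = {}
    n_paths = 0
    for tree_idx, path in paths:
        if not path:
            continue
        n_paths += 1
        nodes.update(path)
        pairs = _ordered_pairs(path)
        if count_mode == "per-tree":
            per_tree.setdefault(tree_idx, set()).update(pairs)
        else:
            for pr in pairs:
                weights[pr] = weights.get(pr, 0) + 1
    if n_paths == 0:
        raise ValueError("no features selected: all paths empty "
                         "(did the ensemble make any splits?)")
    if count_mode == "per-tree":
        for pairs in per_tree.values():
            for pr in pairs:
                weights[pr] = weights.get(pr, 0) + 1
    return DirectedWeightedGraph(nodes=sorted(nodes), edges=weights,
                                 modality=modality)


def reduce_features(X: np.ndarray, graph: DirectedWeightedGraph) -> np.ndarray:
    """Select the graph's node columns from ``X`` in node-list order.

    The graph is fixed per split, so the same column selection applies
    identically to train, validation and test rows.
    """
    X = np.asarray(X)
    bad = [f for f in graph.nodes if f >= X.shape[1] or f < 0]
    if bad:
        raise ValueError(f"graph nodes {bad} absent from matrix columns")
    return X[:, graph.nodes]


def normalize_adjacency(graph: DirectedWeightedGraph) -> np.ndarray:
    """Self-loop-augmented, degree-normalized adjacency.

    With ``A`` the weighted adjacency, forms ``Ã = A + I``, the diagonal
    degree matrix ``D̃`` of row sums of ``Ã``, and returns
    ``D̃^{-1/2} Ã D̃^{-1/2}``. The same row-sum degrees are used on both
    sides even though ``Ã`` may be asymmetric. Self-loops guarantee
    strictly positive row sums, so every entry is finite and >= 0.
    The damping keeps highly connected features from dominating the
    first-layer representation.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    A_tilde = graph.adjacency() + np.eye(graph.n_nodes)
    d = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return inv_sqrt[:, None] * A_tilde * inv_sqrt[None, :]


def symmetrize(graph: DirectedWeightedGraph,
               mode: str = "add") -> DirectedWeightedGraph:
    """Remove directionality: adjacency becomes ``A + Aᵀ`` (default) or
    ``max(A, Aᵀ)``. Not idempotent under ``add`` (weights double)."""
    if mode not in ("add", "max"):
        raise ValueError("mode must be 'add' or 'max'")
    new: dict[tuple[int, int], float] = {}
    for (a, b), w in graph.edges.items():
        for key in ((a, b), (b, a)):
            if mode == "add":
                new[key] = new.get(key, 0) + w
            else:
                new[key] = max(new.get(key, 0), w)
    return DirectedWeightedGraph(nodes=list(graph.nodes), edges=new,
                                 modality=graph.modality)


def graph_stats(graph: DirectedWeightedGraph) -> GraphStats:
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    return GraphStats(node_count=graph.n_nodes, edge_count=graph.n_edges)


# ---------------------------------------------------------------------------
# Graph I/O
# ---------------------------------------------------------------------------

def write_graph(graph: DirectedWeightedGraph, edge_path: str,
                node_path: str) -> None:
    """Edge-list TSV (source, target, weight) + node list preserving order."""
    with open(node_path, "w") as fh:
        fh.write("feature\n")
        for f in graph.nodes:
            fh.write(f"{f}\n")
    with open(edge_path, "w") as fh:
        fh.write("source_feature\ttarget_feature\tweight\n")
        for (a, b), w in sorted(graph.edges.items()):
            fh.write(f"{a}\t{b}\t{w:g}\n")


def read_graph(edge_path: str, node_path: str,
               modality: int = 0) -> DirectedWeightedGraph:
    with open(node_path) as fh:
        next(fh)
        nodes = [int(line.strip()) for line in fh if line.strip()]
    edges: dict[tuple[int, int], float] = {}
    with open(edge_path) as fh:
        next(fh)
        for line in fh:
            if not line.strip():
                continue
            a, b, w = line.split("\t")
            edges[(int(a), int(b))] = float(w)
    return DirectedWeightedGraph(nodes=nodes, edges=edges, modality=modality)


def to_networkx(graph: DirectedWeightedGraph):
    """Export as a ``networkx.DiGraph`` (e.g. for GraphML output)."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    g.add_weighted_edges_from((a, b, w) for (a, b), w in graph.edges.items())
    return g
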