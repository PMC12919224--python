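"""Per-split training, the multi-seed experiment and ablation variants.

Leakage protocol: for every split the tree ensembles — and hence the
graphs, node sets and reduced-feature columns — are fitted on training
rows only; validation and test rows are merely passed through the fixed
column selection. Network weights and batch-norm statistics likewise see
training rows only; early stopping monitors validation loss and the
best-validation weights are restored before the untouched test set is
scored.

Variants: ``full`` (boosted graphs, tensor fusion, directed),
``rf`` (random-forest graph construction), ``con`` (concatenation
instead of tensor fusion) and ``undir`` (symmetrized adjacency) — each
differs from ``full`` in exactly one override, so with shared seeds the
metric difference isolates that component.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .autodiff import Adam
from .data import OmicsDataset, RunConfig, SplitSpec, make_splits
from .graphs import (DirectedWeightedGraph, build_digraph, extract_paths,
                     graph_stats, reduce_features, symmetrize, train_ensemble)
from .metrics import (MetricRecord, compute_metrics, significance_stars,
                      summarize, welch_t)
from .model import MultiOmicsNet

logger = logging.getLogger("treefuse")

__all__ = ["VariantSpec", "TrainResult", "VARIANTS", "build_graphs",
           "run_split", "run_experiment", "aggregate", "fuse_concat"]


@dataclass(frozen=True)
class VariantSpec:
    """A named model variant; non-full variants carry exactly one
    override relative to the full model."""

    name: str
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name != "full" and len(self.overrides) != 1:
            raise ValueError("ablation variants override exactly one knob")

    def apply(self, config: RunConfig) -> RunConfig:
        return config.replace(**self.overrides)


VARIANTS = {
    "full": VariantSpec("full"),
    "rf": VariantSpec("rf", {"estimator": "random-forest"}),
    "con": VariantSpec("con", {"fusion": "concat"}),
    "undir": VariantSpec("undir", {"graph": "undirected"}),
}


@dataclass
class TrainResult:
    model: MultiOmicsNet
    graphs: list[DirectedWeightedGraph]
    record: MetricRecord
    history: dict
    split: SplitSpec


def fuse_concat(Z1: np.ndarray, Z2: np.ndarray, Z3: np.ndarray) -> np.ndarray:
    """Column-wise concatenation of unimodal embeddings (ablation path)."""
    Zs = [np.atleast_2d(np.asarray(Z, dtype=float)) for Z in (Z1, Z2, Z3)]
    if len({Z.shape[0] for Z in Zs}) != 1:
        raise ValueError("embeddings must share the sample dimension")
    return np.concatenate(Zs, axis=1)


def build_graphs(dataset: OmicsDataset, train_rows: np.ndarray,
                 config: RunConfig, seed: int,
                 ) -> tuple[list[DirectedWeightedGraph], list]:
    """Fit one ensemble per modality on training rows and derive graphs."""
    kind = "random-forest" if config.estimator == "random-forest" else "boosted"
    graphs, ensembles = [], []
    y_train = dataset.labels[train_rows]
    for i, X in enumerate(dataset.matrices):
        ens = train_ensemble(X[train_rows], y_train, M=config.tree_count,
                             kind=kind, seed=seed + i)
        g = build_digraph(extract_paths(ens), count_mode=config.count_mode,
                          modality=i)
        if config.graph == "undirected":
            g = symmetrize(g)
        graphs.append(g)
        ensembles.append(ens)
    return graphs, ensembles


def run_split(dataset: OmicsDataset, split: SplitSpec, config: RunConfig,
              variant: VariantSpec | None = None,
              l2_schedule: Callable[[int], float] | None = None,
              ) -> TrainResult:
    """Train and evaluate one model on one stratified split.

    The master seed is ``split.seed``; it governs graph construction,
    weight initialization, minibatch order and dropout. ``l2_schedule``
    maps epoch -> λ (default: constant ``config.l2_lambda``).
    """
    variant = variant or VARIANTS["full"]
    cfg = variant.apply(config)
    seed = int(split.seed)

    graphs, _ = build_graphs(dataset, split.train, cfg, seed=seed)
    stats = [graph_stats(g) for g in graphs]
    logger.info("seed %d variant %s: nodes %s, edge/node %s", seed,
                variant.name, [s.node_count for s in stats],
                [round(s.edge_node_ratio, 2) for s in stats])

    Xstars = [reduce_features(X, g) for X, g in zip(dataset.matrices, graphs)]
    X_tr = [X[split.train] for X in Xstars]
    X_va = [X[split.val] for X in Xstars]
    X_te = [X[split.test] for X in Xstars]
    y_tr = dataset.labels[split.train]
    y_va = dataset.labels[split.val]
    y_te = dataset.labels[split.test]

    model = MultiOmicsNet(graphs, dataset.class_count, cfg, seed=seed + 1000)
    opt = Adam(model.trainable(), lr=cfg.learning_rate)
    rng = np.random.default_rng(seed + 2000)
    model.warm_start_bn(X_tr, rng)
    schedule = l2_schedule or (lambda epoch: cfg.l2_lambda)

    n_tr = y_tr.size
    best_val = np.inf
    best_state = model.state_arrays()
    best_state = {k: v.copy() for k, v in best_state.items()}
    patience_left = cfg.patience
    history = {"train_loss": [], "val_loss": []}

    for epoch in range(cfg.max_epochs):
        lam = schedule(epoch)
        order = rng.permutation(n_tr)
        epoch_loss = 0.0
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, _ = model.loss([X[idx] for X in X_tr], y_tr[idx],
                                 training=True, rng=rng, l2_lambda=lam)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * idx.size
        history["train_loss"].append(epoch_loss / n_tr)

        val_loss, _ = model.loss(X_va, y_va, training=False, l2_lambda=0.0)
        val_loss = float(val_loss.data)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - cfg.min_delta:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
            patience_left = cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    model.load_state_arrays(best_state)
    record = compute_metrics(y_te, model.predict(X_te), seed=seed,
                             variant=variant.name)
    history["graph_stats"] = stats
    history["epochs_run"] = len(history["val_loss"])
    return TrainResult(model=model, graphs=graphs, record=record,
                       history=history, split=split)


def run_experiment(dataset: OmicsDataset, config: RunConfig,
                   variants: Sequence[VariantSpec] | None = None,
                   seeds: Sequence[int] | None = None,
                   ) -> pd.DataFrame:
    """One record per (variant, seed) over independent stratified splits."""
    variants = list(variants) if variants is not None else [VARIANTS["full"]]
    seeds = list(seeds) if seeds is not None else list(config.seeds)
    splits = make_splits(dataset.labels, seeds)
    rows = []
    for split in splits:
        for variant in variants:
            res = run_split(dataset, split, config, variant)
            rows.append(res.record.as_dict())
    return pd.DataFrame(rows)


def aggregate(results: pd.DataFrame, reference: str = "full") -> pd.DataFrame:
    """Mean ± SD [95% CI] per variant and metric, with Welch significance
    stars against the reference variant (when present with >= 2 seeds)."""
    metrics = ["accuracy", "f1_weighted", "f1_macro"]
    out_rows = []
    have_ref = (results["variant"] == reference).sum() >= 2
    for variant, grp in results.groupby("variant", sort=False):
        row: dict = {"variant": variant, "n_seeds": len(grp)}
        for m in metrics:
            s = summarize(grp[m].to_numpy())
            cell = (f"{s.mean:.3f} ± {s.sd:.3f} "
                    f"[{s.ci_low:.3f}, {s.ci_high:.3f}]")
            if have_ref and variant != reference:
                ref_scores = results.loc[results["variant"] == reference, m]
                w = welch_t(ref_scores.to_numpy(), grp[m].to_numpy())
                cell += significance_stars(w.p_greater)
            row[m] = cell
        out_rows.append(row)
    return pd.DataFrame(out_rows)
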