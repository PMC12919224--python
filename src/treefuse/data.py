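"""Domain containers, file I/O, stratified splits and run configuration.

The central object is :class:`OmicsDataset`: three sample-aligned feature
matrices (one per omics modality, e.g. DNA methylation / mRNA / miRNA),
an integer label vector and the bookkeeping needed to keep rows and
columns identifiable across the pipeline.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "OmicsDataset",
    "SplitSpec",
    "RunConfig",
    "read_omics",
    "write_omics",
    "make_splits",
    "load_config",
]


@dataclass
class OmicsDataset:
    """Sample-aligned multi-omics dataset with a multiclass label vector.

    Parameters
    ----------
    matrices
        One ``(n, p_i)`` real matrix per modality (typically three).
    labels
        Integer class labels in ``{0..C-1}``, length ``n``.
    class_count
        Number of classes ``C >= 2``.
    feature_names
        Per-modality feature name lists (length ``p_i`` each).
    sample_ids
        Sample identifiers, length ``n``; row ``k`` of every matrix
        belongs to ``sample_ids[k]``.
    class_names
        Optional mapping from the 0-based internal label to the original
        class name.
    """

    matrices: list[np.ndarray]
    labels: np.ndarray
    class_count: int
    feature_names: list[list[str]]
    sample_ids: list[str]
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrices = [np.asarray(m, dtype=float) for m in self.matrices]
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.n_samples
        for i, m in enumerate(self.matrices):
            if m.ndim != 2 or m.shape[0] != n:
                raise ValueError(
                    f"modality {i} has shape {m.shape}, expected ({n}, p)"
                )
            if len(self.feature_names[i]) != m.shape[1]:
                raise ValueError(f"feature_names[{i}] length mismatch")
        if self.labels.shape != (n,):
            raise ValueError("labels must be a length-n vector")
        if self.class_count < 2:
            raise ValueError("need at least two classes")
        present = set(np.unique(self.labels).tolist())
        if not present <= set(range(self.class_count)):
            raise ValueError("labels outside {0..C-1}")
        if len(present) != self.class_count:
            raise ValueError("every class must occur at least once")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_modalities(self) -> int:
        return len(self.matrices)

    def subset(self, rows: np.ndarray) -> "OmicsDataset":
        """Row subset (used for train/val/test views)."""
        rows = np.asarray(rows, dtype=int)
        return OmicsDataset(
            matrices=[m[rows] for m in self.matrices],
            labels=self.labels[rows],
            class_count=self.class_count,
            feature_names=self.feature_names,
            sample_ids=[self.sample_ids[r] for r in rows],
            class_names=self.class_names,
        )


@dataclass(frozen=True)
class SplitSpec:
    """A stratified train/validation/test partition of ``{0..n-1}``."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int
    fractions: tuple[float, float, float] = (0.60, 0.20, 0.20)

    def __post_init__(self) -> None:
        parts = [np.asarray(p, dtype=int) for p in (self.train, self.val, self.test)]
        object.__setattr__(self, "train", parts[0])
        object.__setattr__(self, "val", parts[1])
        object.__setattr__(self, "test", parts[2])
        all_idx = np.concatenate(parts)
        if len(set(all_idx.tolist())) != all_idx.size:
            raise ValueError("split parts overlap")

    @property
    def n(self) -> int:
        return self.train.size + self.val.size + self.test.size


@dataclass
class RunConfig:
    """Hyperparameters for one training run.

    Defaults are the selected operating point of the method: 100 trees for
    graph construction, width-64 hidden layers, Adam at 1e-4, batch 64,
    up to 1000 epochs with dropout 0.5, L2 strength 0.01, early stopping
    (patience 10, min-delta 1e-3), CP rank 48 and three residual blocks.
    """

    tree_count: int = 100
    estimator: str = "boosted"          # "boosted" | "random-forest"
    hidden_width: int = 64
    branch_depth: int = 1
    learning_rate: float = 0.0001
    batch_size: int = 64
    max_epochs: int = 1000
    dropout_rate: float = 0.5
    l2_lambda: float = 0.01
    patience: int = 10
    min_delta: float = 0.001
    cp_rank: int = 48
    residual_block_count: int = 3
    fusion: str = "tensor"              # "tensor" | "concat"
    graph: str = "directed"             # "directed" | "undirected"
    count_mode: str = "per-tree"        # "per-tree" | "per-path"
    notation_faithful_width: bool = False
    seeds: tuple[int, ...] = tuple(range(20))

    def __post_init__(self) -> None:
        if min(self.tree_count, self.hidden_width, self.batch_size,
               self.max_epochs, self.cp_rank, self.residual_block_count,
               self.patience, self.branch_depth) < 1:
            raise ValueError("all counts must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate in [0, 1)")
        if self.learning_rate <= 0 or self.l2_lambda < 0 or self.min_delta < 0:
            raise ValueError("invalid rate")
        if self.estimator not in ("boosted", "random-forest"):
            raise ValueError("estimator must be boosted|random-forest")
        if self.fusion not in ("tensor", "concat"):
            raise ValueError("fusion must be tensor|concat")
        if self.graph not in ("directed", "undirected"):
            raise ValueError("graph must be directed|undirected")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: str) -> str:
    with open(path, "r", newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def _read_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index = df.index.astype(str)
    try:
        mat = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return mat


def read_omics(paths: Sequence[str], label_path: str) -> OmicsDataset:
    """Read per-modality matrices plus a label file into an aligned dataset.

    Matrices are delimited text with feature names in the first row and
    sample ids in the first column; the label file maps sample id to class.
    Samples missing from any modality (or unlabelled) are dropped
    (complete-case alignment). Class labels are recoded to contiguous
    0-based integers in sorted order of the original names.
    """
    frames = [_read_matrix(p) for p in paths]
    lab = pd.read_csv(label_path, sep=_sniff_sep(label_path), index_col=0)
    lab.index = lab.index.astype(str)
    label_col = lab.iloc[:, 0].astype(str)

    keep = [s for s in frames[0].index
            if all(s in f.index for f in frames) and s in label_col.index]
    if not keep:
        raise ValueError("no samples shared by all modalities and the label file")
    frames = [f.loc[keep] for f in frames]
    label_values = label_col.loc[keep]

    class_names = sorted(label_values.unique().tolist())
    mapping = {c: i for i, c in enumerate(class_names)}
    labels = np.array([mapping[v] for v in label_values], dtype=int)

    return OmicsDataset(
        matrices=[f.to_numpy(dtype=float) for f in frames],
        labels=labels,
        class_count=len(class_names),
        feature_names=[list(f.columns.astype(str)) for f in frames],
        sample_ids=list(keep),
        class_names=class_names,
    )


def write_omics(dataset: OmicsDataset, dir_path: str,
                prefix: str = "modality", sep: str = "\t") -> tuple[list[str], str]:
    """Write a dataset to ``<dir>/<prefix><i>.tsv`` plus ``labels.tsv``.

    Returns the matrix paths and the label path; ``read_omics`` on these
    files reconstructs the dataset (up to text float precision).
    """
    os.makedirs(dir_path, exist_ok=True)
    paths = []
    for i, (m, names) in enumerate(zip(dataset.matrices, dataset.feature_names), 1):
        df = pd.DataFrame(m, index=dataset.sample_ids, columns=names)
        p = os.path.join(dir_path, f"{prefix}{i}.tsv")
        df.to_csv(p, sep=sep, index_label="sample_id", float_format="%.10g")
        paths.append(p)
    label_path = os.path.join(dir_path, "labels.tsv")
    names = dataset.class_names or [str(c) for c in range(dataset.class_count)]
    lab = pd.DataFrame(
        {"label": [names[c] for c in dataset.labels]}, index=dataset.sample_ids
    )
    lab.to_csv(label_path, sep=sep, index_label="sample_id")
    return paths, label_path


# ---------------------------------------------------------------------------
# Stratified splits
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([-(r - c) for r, c in zip(raw, counts)], kind="stable")
    for k in range(rem):
        counts[order[k]] += 1
    return counts


def make_splits(labels: np.ndarray, seeds: Sequence[int],
                fractions: tuple[float, float, float] = (0.60, 0.20, 0.20),
                ) -> list[SplitSpec]:
    """Stratified train/validation/test splits, one per seed.

    Within every class the indices are shuffled with the seed and sliced
    into proportional blocks (largest-remainder rounding), so per-class
    counts in each part deviate from exact proportionality by at most one
    sample and identical seeds give identical splits.
    """
    labels = np.asarray(labels, dtype=int)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < len(fractions):
        raise ValueError(
            f"class {classes[counts.argmin()]} has {counts.min()} samples, "
            f"fewer than the {len(fractions)} split parts"
        )
    specs = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        parts: list[list[int]] = [[], [], []]
        for c in classes:
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            n_tr, n_va, n_te = _largest_remainder(idx.size, fractions)
            parts[0].extend(idx[:n_tr].tolist())
            parts[1].extend(idx[n_tr:n_tr + n_va].tolist())
            parts[2].extend(idx[n_tr + n_va:].tolist())
        specs.append(SplitSpec(
            train=np.sort(parts[0]), val=np.sort(parts[1]),
            test=np.sort(parts[2]), seed=int(seed), fractions=fractions,
        ))
    return specs


def load_config(path: str | None = None, **overrides) -> RunConfig:
    """Load a ``key: value`` YAML config file, applying keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    if "seeds" in data:
        data["seeds"] = tuple(int(s) for s in data["seeds"])
    return RunConfig(**data)
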