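"""Synthetic three-modality omics generator with planted signal.

Emulates the statistical shape of preprocessed multi-omics subtype data:
three modalities of heterogeneous [0,1]-scaled features, small-n/large-p
(hundreds of samples, hundreds to thousands of features), optional class
imbalance mirroring real cohorts, a chosen number of class-informative
features per modality, and an optional purely multiplicative trimodal
signal in which no single modality carries marginal information.

Every feature is a logistic squash of a Gaussian latent — values are
strictly inside (0, 1) and additive effects keep an interpretable scale.
Per-feature random offsets and scales give the heterogeneous marginal
distributions seen across real omics layers; no attempt is made to mimic
platform-specific shapes (methylation beta bimodality, count skew)
beyond range and heterogeneity.

Ground truth (informative feature ids, target classes, latent factors)
ships with the dataset so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import OmicsDataset, _largest_remainder

__all__ = ["SimSpec", "generate", "imbalance_preset"]

_PRESETS = {
    # class sizes of two real cohorts used as imbalance templates:
    # a 5-subtype breast cohort and a 3-subtype endometrial cohort
    "brca-like": (115, 131, 46, 436, 147),
    "ucec-like": (311, 98, 21),
}


def imbalance_preset(name: str) -> np.ndarray:
    """Class proportions mirroring real cohort imbalance."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(_PRESETS)}")
    counts = np.array(_PRESETS[name], dtype=float)
    return counts / counts.sum()


@dataclass
class SimSpec:
    """Generator settings.

    ``delta`` is the additive class effect (on the pre-squash latent
    scale, where the noise SD is ``noise_scale``); ``interaction`` is
    ``"none"`` or ``"trimodal-product"`` (binary labels decided by the
    sign of the product of one ±1 latent per modality, so each single
    modality is marginally uninformative).
    """

    n: int = 300
    p: tuple[int, int, int] = (200, 200, 200)
    class_count: int = 3
    proportions: tuple[float, ...] | None = None
    k_informative: tuple[int, int, int] = (10, 10, 10)
    delta: float = 1.5
    interaction: str = "none"
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interaction not in ("none", "trimodal-product"):
            raise ValueError("interaction must be 'none' or 'trimodal-product'")
        if self.interaction == "trimodal-product" and self.class_count != 2:
            raise ValueError("trimodal-product mode is a two-class rule")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        for k, p in zip(self.k_informative, self.p):
            if k > p:
                raise ValueError("k_informative exceeds feature count")
        if self.proportions is not None:
            props = np.asarray(self.proportions, dtype=float)
            if props.size != self.class_count or abs(props.sum() - 1) > 1e-9:
                raise ValueError("proportions must sum to 1, one per class")
            if (props * self.n < 1).any():
                raise ValueError("a class would receive zero samples")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate(spec: SimSpec) -> tuple[OmicsDataset, dict]:
    """Draw a dataset plus ground-truth metadata, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n, C = spec.n, spec.class_count

    # labels
    if spec.interaction == "trimodal-product":
        latents = rng.choice([-1.0, 1.0], size=(n, 3))
        labels = (latents.prod(axis=1) > 0).astype(int)
        # guard the degenerate draw where one class is absent
        if np.unique(labels).size < 2:
            latents[0] *= -1
            labels = (latents.prod(axis=1) > 0).astype(int)
    else:
        latents = None
        props = (np.full(C, 1.0 / C) if spec.proportions is None
                 else np.asarray(spec.proportions, dtype=float))
        counts = _largest_remainder(n, props)
        labels = np.repeat(np.arange(C), counts)
        rng.shuffle(labels)

    matrices, informative, targets = [], [], []
    for mod in range(3):
        p_mod = spec.p[mod]
        k = spec.k_informative[mod]
        ids = np.sort(rng.choice(p_mod, size=k, replace=False))
        tgt = np.arange(k) % C  # informative feature -> class it marks
        offset = rng.uniform(-1.0, 1.0, size=p_mod)
        scale = rng.uniform(0.5, 1.5, size=p_mod)
        z = offset + scale * spec.noise_scale * rng.standard_normal((n, p_mod))
        if spec.interaction == "trimodal-product":
            # informative features carry this modality's +-1 factor only
            z[:, ids] += spec.delta * latents[:, [mod]]
        else:
            for j, c in zip(ids, tgt):
                z[labels == c, j] += spec.delta
        matrices.append(_sigmoid(z))
        informative.append(ids)
        targets.append(tgt)

    dataset = OmicsDataset(
        matrices=matrices,
        labels=labels,
        class_count=C,
        feature_names=[[f"m{mod + 1}_f{j}" for j in range(spec.p[mod])]
                       for mod in range(3)],
        sample_ids=[f"s{i:04d}" for i in range(n)],
        class_names=[f"class{c}" for c in range(C)],
    )
    truth = {
        "informative": informative,
        "target_class": targets,
        "latents": latents,
        "spec": spec,
    }
    return dataset, truth


def oracle_interaction_accuracy(truth: dict, labels: np.ndarray) -> float:
    """Accuracy of the ground-truth three-way rule (sanity oracle)."""
    latents = truth["latents"]
    if latents is None:
        raise ValueError("dataset was not generated in trimodal-product mode")
    pred = (latents.prod(axis=1) > 0).astype(int)
    return float(np.mean(pred == np.asarray(labels)))
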