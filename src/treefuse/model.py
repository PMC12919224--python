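"""End-to-end model: three graph-masked branches, fusion, residual head.

Two fusion modes are supported. ``tensor`` (default) augments each
unimodal embedding with a constant 1 and combines them through the
rank-R CP parameterization (λ and modality projections P_i), so the
fused vector carries unimodal, bimodal and trimodal multiplicative
interactions at linear cost. ``concat`` is the ablation path: the
unaugmented embeddings are concatenated column-wise and handed straight
to the residual head, whose first (projection) block maps them to the
hidden width.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, softmax_cross_entropy
from .data import RunConfig
from .encoder import BranchParams, glorot
from .fusion import FusionParams
from .graphs import DirectedWeightedGraph, normalize_adjacency
from .residual import HeadParams, _softmax

__all__ = ["MultiOmicsNet"]


@dataclass
class _FusionTensors:
    lam: Tensor
    projections: list[Tensor]


class MultiOmicsNet:
    """Trainable multi-omics classifier over fixed per-modality graphs."""

    def __init__(self, graphs: list[DirectedWeightedGraph], n_classes: int,
                 config: RunConfig, seed: int = 0):
        self.config = config
        self.n_classes = n_classes
        self.graphs = graphs
        rng = np.random.default_rng(seed)
        latent = None if config.notation_faithful_width else config.hidden_width
        self.branches = [
            BranchParams.init(normalize_adjacency(g), latent,
                              config.branch_depth, config.dropout_rate, rng)
            for g in graphs
        ]
        widths = [b.latent_width for b in self.branches]
        if config.fusion == "tensor":
            fp = FusionParams.init(config.cp_rank, widths, rng)
            self.fusion = _FusionTensors(
                lam=Tensor(fp.lam, requires_grad=True),
                projections=[Tensor(P, requires_grad=True)
                             for P in fp.projections],
            )
            head_in = config.cp_rank
        else:
            self.fusion = None
            head_in = sum(widths)
        self.head = HeadParams.init(head_in, config.hidden_width,
                                    config.residual_block_count,
                                    n_classes, rng)

    # -- parameter bookkeeping --------------------------------------------
    def trainable(self) -> list[Tensor]:
        out: list[Tensor] = []
        for b in self.branches:
            out.extend(b.trainable())
        if self.fusion is not None:
            out.append(self.fusion.lam)
            out.extend(self.fusion.projections)
        out.extend(self.head.trainable())
        return out

    def weight_matrices(self) -> list[Tensor]:
        """L2-regularized set: all weight matrices of branches, fusion
        projections and head; biases, BN parameters and λ excluded."""
        out: list[Tensor] = []
        for b in self.branches:
            out.extend(b.weight_matrices())
        if self.fusion is not None:
            out.extend(self.fusion.projections)
        out.extend(self.head.weight_matrices())
        return out

    def warm_start_bn(self, Xstars: list[np.ndarray],
                      rng: np.random.Generator) -> None:
        """Initialize BN running statistics from one training-mode pass.

        Without this the running moments start at (0, 1) and lag the true
        activation statistics for the first dozens of epochs, which
        distorts inference-mode validation loss early in training. Uses
        training rows only (call before the first optimizer step).
        """
        for branch, X in zip(self.branches, Xstars):
            momentum = branch.bn_momentum
            branch.bn_momentum = 0.0
            branch.forward(Tensor(np.asarray(X, dtype=float)),
                           training=True, rng=rng)
            branch.bn_momentum = momentum

    # -- forward -----------------------------------------------------------
    def fuse(self, Zs: list[Tensor]) -> Tensor:
        if self.fusion is None:
            return concat(Zs, axis=1)
        parts = []
        for Z, P in zip(Zs, self.fusion.projections):
            n = Z.shape[0]
            Zaug = concat([Z, Tensor(np.ones((n, 1)))], axis=1)
            parts.append(Zaug @ _transpose(P))
        h = parts[0] * parts[1] * parts[2] * self.fusion.lam
        return h

    def forward(self, Xstars: list[np.ndarray], training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        Zs = [b.forward(Tensor(np.asarray(X, dtype=float)), training, rng)
              for b, X in zip(self.branches, Xstars)]
        return self.head.forward(self.fuse(Zs))

    def loss(self, Xstars: list[np.ndarray], labels: np.ndarray,
             training: bool = True,
             rng: np.random.Generator | None = None,
             l2_lambda: float | None = None) -> tuple[Tensor, np.ndarray]:
        logits = self.forward(Xstars, training=training, rng=rng)
        onehot = np.eye(self.n_classes)[np.asarray(labels, dtype=int)]
        loss, probs = softmax_cross_entropy(logits, onehot)
        lam = self.config.l2_lambda if l2_lambda is None else l2_lambda
        if lam > 0:
            reg = None
            for w in self.weight_matrices():
                term = (w * w).sum()
                reg = term if reg is None else reg + term
            loss = loss + Tensor(lam) * reg
        return loss, probs

    def predict_proba(self, Xstars: list[np.ndarray]) -> np.ndarray:
        return _softmax(self.forward(Xstars, training=False).data)

    def predict(self, Xstars: list[np.ndarray]) -> np.ndarray:
        return self.predict_proba(Xstars).argmax(axis=1)

    # -- checkpointing -----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.data for i, p in enumerate(self.trainable())}
        for bi, b in enumerate(self.branches):
            for k in range(len(b.dense)):
                state[f"bn_mean_{bi}_{k}"] = b.bn_mean[k]
                state[f"bn_var_{bi}_{k}"] = b.bn_var[k]
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.trainable()):
            p.data = np.array(state[f"param_{i}"])
        for bi, b in enumerate(self.branches):
            for k in range(len(b.dense)):
                b.bn_mean[k] = np.array(state[f"bn_mean_{bi}_{k}"])
                b.bn_var[k] = np.array(state[f"bn_var_{bi}_{k}"])

    def save(self, path: str) -> None:
        """Single-file checkpoint of all named arrays."""
        np.savez(path, **self.state_arrays())

    def load(self, path: str) -> None:
        with np.load(path) as data:
            self.load_state_arrays(dict(data))


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, t.requires_grad)
    out._parents = (t,)

    def bw():
        t._accum(out.grad.T)
    out._backward = bw
    return out
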