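"""Residual classification head and the joint training objective.

The fused embedding passes through a stack of residual blocks of fixed
hidden width (64 by default). Each block computes

    out = σ(σ(σ(X W1) W2) W3 + X)

with σ = ReLU; when the block's input width differs from the hidden
width (only possible for the first block, since the width is fixed
thereafter) the input is first linearly projected and the projected
input is used both in the first product and the skip connection. A final
linear layer maps to class logits; softmax yields probabilities.

The objective is mean categorical cross-entropy plus an L2 penalty of
strength λ over every trainable weight matrix of the whole model
(branches, fusion projections and head; biases and batch-norm parameters
excluded). λ may vary over epochs through a schedule hook; the default
schedule is constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, softmax_cross_entropy
from .encoder import glorot

__all__ = ["ResidualBlock", "HeadParams", "LossSpec",
           "residual_block_forward", "classify", "total_loss"]


@dataclass
class ResidualBlock:
    """One identity or projection residual block.

    ``P_in`` is the input-projection matrix (projection blocks only);
    identity blocks require matching input and hidden widths.
    """

    W1: Tensor
    W2: Tensor
    W3: Tensor
    P_in: Tensor | None = None

    @property
    def kind(self) -> str:
        return "identity" if self.P_in is None else "projection"

    @classmethod
    def init(cls, in_width: int, width: int,
             rng: np.random.Generator) -> "ResidualBlock":
        P_in = None
        if in_width != width:
            P_in = Tensor(glorot(rng, in_width, width), requires_grad=True)
        return cls(
            W1=Tensor(glorot(rng, width, width), requires_grad=True),
            W2=Tensor(glorot(rng, width, width), requires_grad=True),
            W3=Tensor(glorot(rng, width, width), requires_grad=True),
            P_in=P_in,
        )

    def forward(self, X: Tensor) -> Tensor:
        if self.P_in is not None:
            X = X @ self.P_in
        elif X.shape[1] != self.W1.shape[0]:
            raise ValueError(
                f"identity block needs input width {self.W1.shape[0]}, "
                f"got {X.shape[1]}")
        h = (X @ self.W1).relu()
        h = (h @ self.W2).relu()
        return (h @ self.W3 + X).relu()

    def trainable(self) -> list[Tensor]:
        out = [self.W1, self.W2, self.W3]
        if self.P_in is not None:
            out.append(self.P_in)
        return out


@dataclass
class HeadParams:
    """Residual blocks plus the final softmax layer."""

    blocks: list[ResidualBlock]
    W_out: Tensor
    b_out: Tensor

    @classmethod
    def init(cls, in_width: int, width: int, n_blocks: int, n_classes: int,
             rng: np.random.Generator) -> "HeadParams":
        if n_blocks < 1:
            raise ValueError("need at least one residual block")
        blocks = [ResidualBlock.init(in_width, width, rng)]
        blocks += [ResidualBlock.init(width, width, rng)
                   for _ in range(n_blocks - 1)]
        return cls(
            blocks=blocks,
            W_out=Tensor(glorot(rng, width, n_classes), requires_grad=True),
            b_out=Tensor(np.zeros(n_classes), requires_grad=True),
        )

    def forward(self, X: Tensor) -> Tensor:
        for blk in self.blocks:
            X = blk.forward(X)
        return X @ self.W_out + self.b_out

    def trainable(self) -> list[Tensor]:
        out = []
        for blk in self.blocks:
            out.extend(blk.trainable())
        out.extend([self.W_out, self.b_out])
        return out

    def weight_matrices(self) -> list[Tensor]:
        out = []
        for blk in self.blocks:
            out.extend(blk.trainable())  # blocks have no biases
        out.append(self.W_out)
        return out


@dataclass
class LossSpec:
    """L2 strength and the set of regularized weight matrices."""

    l2_lambda: float = 0.01
    weights: list[Tensor] | None = None

    def __post_init__(self) -> None:
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def residual_block_forward(X: np.ndarray, block: ResidualBlock) -> np.ndarray:
    """Apply one residual block to a plain array."""
    return block.forward(Tensor(np.atleast_2d(np.asarray(X, dtype=float)))).data


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def classify(fused: np.ndarray, head: HeadParams) -> np.ndarray:
    """Class probabilities for fused embeddings (rows sum to 1)."""
    logits = head.forward(Tensor(np.atleast_2d(np.asarray(fused, dtype=float))))
    return _softmax(logits.data)


def total_loss(probs: np.ndarray, labels: np.ndarray,
               weights: list[np.ndarray] | None = None,
               l2_lambda: float = 0.0, clip: float = 1e-12) -> float:
    """Mean cross-entropy plus λ · Σ w² over the regularized matrices."""
    probs = np.asarray(probs, dtype=float)
    if not np.all(np.isfinite(probs)):
        raise ValueError("non-finite probabilities")
    labels = np.asarray(labels, dtype=int)
    n = probs.shape[0]
    ce = -np.mean(np.log(np.clip(probs[np.arange(n), labels], clip, 1.0)))
    reg = 0.0
    for w in (weights or []):
        arr = w.data if isinstance(w, Tensor) else np.asarray(w)
        reg += float(np.sum(arr ** 2))
    return float(ce + l2_lambda * reg)
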