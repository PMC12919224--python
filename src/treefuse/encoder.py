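"""Graph-embedded neural branch for one omics modality.

The first hidden layer is square (p* -> p*) and Hadamard-masked by the
normalized adjacency N = D̃^{-1/2}(A+I)D̃^{-1/2} of the modality's
directed weighted feature graph:

    H1 = ReLU(X* (W ⊙ N) + b)

so an input feature only feeds the hidden units it is graph-connected to
(plus itself through the self-loop), and high-degree features are damped
by the normalization. A dense ReLU layer (default width 64, with batch
normalization and dropout during training) then produces the unimodal
embedding Z fed to fusion. With ``latent_width=None`` the branch is
"notation-faithful": Z is the masked-layer output itself (width p*).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

__all__ = ["BranchParams", "graph_embedded_layer", "encode", "glorot"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Symmetric uniform init scaled by fan-in/fan-out."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


@dataclass
class BranchParams:
    """Trainable parameters of one graph-embedded branch.

    ``W``/``b`` are the masked first layer (p* x p*); ``N`` is the fixed
    normalized adjacency; ``support`` its nonzero pattern. ``dense``
    holds (weight, bias) pairs mapping to the latent width, each followed
    by batch normalization (``bn_gamma``/``bn_beta`` with running
    statistics) and ReLU; dropout applies after activation when training.
    """

    W: Tensor
    b: Tensor
    N: np.ndarray
    support: np.ndarray
    dense: list[tuple[Tensor, Tensor]]
    bn_gamma: list[Tensor]
    bn_beta: list[Tensor]
    bn_mean: list[np.ndarray]
    bn_var: list[np.ndarray]
    dropout_rate: float = 0.5
    bn_momentum: float = 0.9

    @classmethod
    def init(cls, N: np.ndarray, latent_width: int | None, depth: int,
             dropout_rate: float, rng: np.random.Generator) -> "BranchParams":
        p = N.shape[0]
        # Support-aware first-layer init: the effective weight is W ⊙ N, so a
        # hidden unit's true fan-in is its graph degree, not p*, and each
        # connection is damped by the normalization. Scale the raw weights by
        # a degree-based Glorot limit divided by the local N magnitude so the
        # effective connections start at a healthy scale.
        support = (np.asarray(N) != 0)
        fan_in = support.sum(axis=0)
        fan_out = support.sum(axis=1)
        limit = np.sqrt(6.0 / (fan_in[None, :] + fan_out[:, None]))
        damping = np.where(support, np.abs(N), 1.0)
        W0 = rng.uniform(-1.0, 1.0, size=(p, p)) * limit / damping
        dense, gammas, betas, means, variances = [], [], [], [], []
        if latent_width is not None:
            w_in = p
            for _ in range(depth):
                dense.append((
                    Tensor(glorot(rng, w_in, latent_width), requires_grad=True),
                    Tensor(np.zeros(latent_width), requires_grad=True),
                ))
                gammas.append(Tensor(np.ones(latent_width), requires_grad=True))
                betas.append(Tensor(np.zeros(latent_width), requires_grad=True))
                means.append(np.zeros(latent_width))
                variances.append(np.ones(latent_width))
                w_in = latent_width
        return cls(
            W=Tensor(W0, requires_grad=True),
            b=Tensor(np.zeros(p), requires_grad=True),
            N=np.asarray(N, dtype=float),
            support=support.astype(float),
            dense=dense, bn_gamma=gammas, bn_beta=betas,
            bn_mean=means, bn_var=variances, dropout_rate=dropout_rate,
        )

    @property
    def latent_width(self) -> int:
        return self.dense[-1][0].shape[1] if self.dense else self.N.shape[0]

    def trainable(self) -> list[Tensor]:
        out = [self.W, self.b]
        for w, b in self.dense:
            out.extend([w, b])
        out.extend(self.bn_gamma)
        out.extend(self.bn_beta)
        return out

    def weight_matrices(self) -> list[Tensor]:
        """Arrays subject to L2 (weights only; biases and BN excluded)."""
        return [self.W] + [w for w, _ in self.dense]

    # -- forward -----------------------------------------------------------
    def masked_layer(self, X: Tensor) -> Tensor:
        return (X @ (self.W * Tensor(self.N)) + self.b).relu()

    def forward(self, X: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        h = self.masked_layer(X)
        for k, (w, b) in enumerate(self.dense):
            pre = h @ w + b
            pre = self._batch_norm(pre, k, training)
            h = pre.relu()
            if training and self.dropout_rate > 0:
                if rng is None:
                    raise ValueError("training forward requires an rng")
                keep = 1.0 - self.dropout_rate
                mask = (rng.random(h.shape) < keep) / keep
                h = h * Tensor(mask)
        return h

    def _batch_norm(self, x: Tensor, k: int, training: bool,
                    eps: float = 1e-5) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            m = self.bn_momentum
            self.bn_mean[k] = m * self.bn_mean[k] + (1 - m) * mu.data.ravel()
            self.bn_var[k] = m * self.bn_var[k] + (1 - m) * var.data.ravel()
            xn = xc / (var + eps).sqrt()
        else:
            xn = (x - Tensor(self.bn_mean[k])) / Tensor(
                np.sqrt(self.bn_var[k] + eps))
        return xn * self.bn_gamma[k] + self.bn_beta[k]


# ---------------------------------------------------------------------------
# Functional surface (numpy in, numpy out)
# ---------------------------------------------------------------------------

def graph_embedded_layer(Xstar: np.ndarray, params: BranchParams) -> np.ndarray:
    """H1 = ReLU(X* (W ⊙ N) + b) for a plain array input."""
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    if Xstar.shape[1] != params.N.shape[0]:
        raise ValueError(
            f"input width {Xstar.shape[1]} != graph size {params.N.shape[0]}")
    return params.masked_layer(Tensor(Xstar)).data


def encode(Xstar: np.ndarray, params: BranchParams,
           training: bool = False,
           rng: np.random.Generator | None = None) -> np.ndarray:
    """Unimodal embedding Z for a plain array input.

    Inference (``training=False``) is deterministic: dropout off, batch
    normalization uses running statistics.
    """
    Xstar = np.atleast_2d(np.asarray(Xstar, dtype=float))
    return params.forward(Tensor(Xstar), training=training, rng=rng).data
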