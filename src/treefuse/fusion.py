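"""Tensor fusion of modality embeddings with low-rank CP parameterization.

Each modality embedding is augmented with a constant 1 (appended LAST),
so the per-sample outer product T = z1* ⊗ z2* ⊗ z3* contains the
unimodal, bimodal and trimodal interaction blocks as sub-arrays: fixing
the 1-index of two modalities recovers a unimodal block, of one modality
a bimodal block, and the remaining entries carry the full three-way
products. Materializing T costs Π(d_i+1) per sample, so the model never
forms it: the weight tensor is parameterized in CP form (scale vector λ
and modality-specific projections P_i), which collapses the contraction
to ``h_r = λ_r (P1 z1*)_r (P2 z2*)_r (P3 z3*)_r`` at O(R·Σ(d_i+1)).

``full_tensor`` and ``cp_reconstruct`` exist as brute-force oracles for
small dimensions; training touches only the low-rank path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FusionParams",
    "augment",
    "full_tensor",
    "lowrank_fuse",
    "cp_reconstruct",
    "max_rank_bound",
    "ORACLE_CAP",
]

ORACLE_CAP = 10 ** 6  # max elements for explicitly materialized tensors


@dataclass
class FusionParams:
    """Rank-R CP fusion parameters.

    ``lam`` is the trainable scale vector (length R, initialized to 1);
    ``projections`` holds P_i of shape (R, d_i + 1) mapping each
    augmented embedding into rank space.
    """

    lam: np.ndarray
    projections: list[np.ndarray]

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.projections = [np.asarray(P, dtype=float) for P in self.projections]
        R = self.lam.shape[0]
        for i, P in enumerate(self.projections):
            if P.ndim != 2 or P.shape[0] != R:
                raise ValueError(f"P{i + 1} must have {R} rows, got {P.shape}")

    @property
    def rank(self) -> int:
        return self.lam.shape[0]

    @classmethod
    def init(cls, rank: int, dims: list[int],
             rng: np.random.Generator) -> "FusionParams":
        """Glorot-style random projections, λ = 1."""
        projs = []
        for d in dims:
            limit = np.sqrt(6.0 / (rank + d + 1))
            projs.append(rng.uniform(-limit, limit, size=(rank, d + 1)))
        return cls(lam=np.ones(rank), projections=projs)


def augment(Z: np.ndarray) -> np.ndarray:
    """Append a constant-1 column (LAST) to an (n, d) embedding matrix.

    The appended 1 makes the lower-order (unimodal/bimodal) interaction
    terms appear inside the trimodal outer product.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    return np.concatenate([Z, np.ones((Z.shape[0], 1))], axis=1)


def _check_cap(*dims: int) -> None:
    size = int(np.prod(dims))
    if size > ORACLE_CAP:
        raise ValueError(
            f"explicit tensor of {size} elements exceeds the oracle cap "
            f"({ORACLE_CAP}); use the low-rank path (lowrank_fuse)"
        )


def full_tensor(z1: np.ndarray, z2: np.ndarray, z3: np.ndarray) -> np.ndarray:
    """Per-sample third-order fusion tensor T[a,b,c] = z1[a]·z2[b]·z3[c].

    Oracle only: intended for augmented vectors of small dimension.
    """
    z1, z2, z3 = (np.asarray(z, dtype=float).ravel() for z in (z1, z2, z3))
    _check_cap(z1.size, z2.size, z3.size)
    return np.einsum("a,b,c->abc", z1, z2, z3)


def lowrank_fuse(z1: np.ndarray, z2: np.ndarray, z3: np.ndarray,
                 params: FusionParams) -> np.ndarray:
    """Rank-R fused embedding h with h_r = λ_r·(P1 z1)_r·(P2 z2)_r·(P3 z3)_r.

    Accepts single augmented vectors (returns shape (R,)) or batches of
    shape (n, d_i+1) (returns (n, R)). Never materializes the full
    tensor: cost is O(R · Σ(d_i+1)) multiply-adds per sample.
    """
    zs = [np.asarray(z, dtype=float) for z in (z1, z2, z3)]
    single = zs[0].ndim == 1
    zs = [np.atleast_2d(z) for z in zs]
    P1, P2, P3 = params.projections
    h = params.lam * (zs[0] @ P1.T) * (zs[1] @ P2.T) * (zs[2] @ P3.T)
    return h[0] if single else h


def cp_reconstruct(params: FusionParams) -> np.ndarray:
    """Explicit weight tensor W[a,b,c] = Σ_r λ_r P1[r,a] P2[r,b] P3[r,c].

    Brute-force oracle (sum of R rank-one tensors); subject to the size
    cap like :func:`full_tensor`.
    """
    P1, P2, P3 = params.projections
    _check_cap(P1.shape[1], P2.shape[1], P3.shape[1])
    return np.einsum("r,ra,rb,rc->abc", params.lam, P1, P2, P3)


def max_rank_bound(d1: int, d2: int, d3: int) -> int:
    """Upper bound on the rank of a (d1, d2, d3) tensor:
    min(d1·d2, d1·d3, d2·d3)."""
    if min(d1, d2, d3) <= 0:
        raise ValueError("dimensions must be positive")
    return min(d1 * d2, d1 * d3, d2 * d3)
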