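"""Loss components of the coupled objective.

The total objective (minimisation form) is

    L = (L_Ag + beta KL_g + L_Xg) + (L_Ac + beta KL_c + L_Xc) + w L_orth

where L_A* are class-weighted Bernoulli cross-entropies of the reconstructed
adjacency (the negative expected log-likelihood term of the ELBO), KL* the
per-node-mean KL divergences to the standard-normal prior, L_X* the
per-entry mean squared expression reconstruction errors, and L_orth the
mean squared deviation of the cross-autoencoder cosine-similarity matrix S
from the identity.  S_ij compares cell i's reconstructed profile from the
cell-level decoder with cell j's profile from the gene-level decoder;
driving S to I aligns the two autoencoders on every cell while decorrelating
distinct cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossBreakdown",
    "graph_reconstruction_loss",
    "expression_loss",
    "similarity_matrix",
    "orthogonal_loss",
    "total_loss",
]

_EPS = 1e-7


@dataclass
class LossBreakdown:
    """All components of one evaluation of the objective."""

    graph_g: float = 0.0
    kl_g: float = 0.0
    expr_g: float = 0.0
    graph_c: float = 0.0
    kl_c: float = 0.0
    expr_c: float = 0.0
    orth: float = 0.0
    beta: float = 1.0
    orth_weight: float = 1.0

    @property
    def gene_level(self) -> float:
        return self.graph_g + self.beta * self.kl_g + self.expr_g

    @property
    def cell_level(self) -> float:
        return self.graph_c + self.beta * self.kl_c + self.expr_c

    @property
    def total(self) -> float:
        return self.gene_level + self.cell_level + self.orth_weight * self.orth

    def as_dict(self) -> dict[str, float]:
        return {
            "graph_g": self.graph_g,
            "kl_g": self.kl_g,
            "expr_g": self.expr_g,
            "graph_c": self.graph_c,
            "kl_c": self.kl_c,
            "expr_c": self.expr_c,
            "orth": self.orth,
            "total": self.total,
        }


def graph_reconstruction_loss(
    probs: np.ndarray,
    A: np.ndarray,
    pos_weight: float = 1.0,
    norm: float = 1.0,
) -> float:
    """Class-weighted Bernoulli cross-entropy over all ordered node pairs.

    ``norm * mean(pos_weight * A * (-log p) + (1 - A) * (-log(1 - p)))``
    with probabilities clipped to [1e-7, 1 - 1e-7].  With
    ``pos_weight = norm = 1`` this is the negative mean log-likelihood
    of the adjacency under the decoder.
    """
    probs = np.asarray(probs, dtype=float)
    A = np.asarray(A, dtype=float)
    if probs.shape != A.shape:
        raise ValueError("probs and adjacency shapes differ")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probs outside [0, 1]")
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    ce = pos_weight * A * (-np.log(p)) + (1.0 - A) * (-np.log1p(-p))
    return float(norm * ce.mean())


def expression_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Squared Frobenius norm of the reconstruction error divided by m*n."""
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValueError("shape mismatch between X and X_hat")
    return float(np.mean((X - X_hat) ** 2))


def similarity_matrix(X_hat_c: np.ndarray, X_hat_g: np.ndarray) -> np.ndarray:
    """Cosine similarities S_ij between reconstructed per-cell profiles.

    Both inputs are genes x cells.  Column i of ``X_hat_c`` is cell i as
    reconstructed by the cell-level decoder; column j of ``X_hat_g`` is cell
    j as reconstructed by the gene-level decoder.  Zero-norm columns yield
    similarity 0 by convention.
    """
    U = np.asarray(X_hat_c, dtype=float)
    V = np.asarray(X_hat_g, dtype=float)
    if U.shape != V.shape:
        raise ValueError("reconstructions must share the genes x cells shape")
    nu = np.linalg.norm(U, axis=0)
    nv = np.linalg.norm(V, axis=0)
    denom = np.outer(nu, nv)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = (U.T @ V) / denom
    S[denom == 0] = 0.0
    return S


def orthogonal_loss(S: np.ndarray) -> float:
    """Mean over all n^2 entries of (S - I)^2."""
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    return float(np.mean((S - np.eye(S.shape[0])) ** 2))


def total_loss(parts: LossBreakdown) -> float:
    """Total objective; identical to ``parts.total``."""
    return parts.total
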