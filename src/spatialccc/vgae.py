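"""Variational directed graph autoencoder primitives.

The encoder is a two-layer graph convolution GCN(A, X) = A_n ReLU(A_n X W0) W1
over the out-degree row-normalised adjacency A_n = D_out^{-1}(A + I), with
the mean and log-std heads sharing the first-layer weights W0.  The graph
decoder splits each latent code into a source half and a target half and
emits directed edge probabilities sigma(<z_i^(s), z_j^(t)>), so even a
symmetric input adjacency is decoded into an asymmetric (directed) graph.
Expression is reconstructed from the same codes by a two-layer dense network
(ReLU hidden, linear output).

All functions are plain NumPy and deterministic given their inputs; sampling
takes an explicit seed or generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EncoderParams",
    "EncoderOutput",
    "ExpressionDecoderParams",
    "normalize_adjacency",
    "encode",
    "sample_latent",
    "decode_graph",
    "decode_expression",
    "kl_divergence",
    "sigmoid",
    "relu",
]


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class EncoderParams:
    """Two-layer GCN weights; W0 is shared by the mean and log-std heads."""

    W0: np.ndarray
    W1_mu: np.ndarray
    W1_sigma: np.ndarray

    def __post_init__(self) -> None:
        if self.W1_mu.shape != self.W1_sigma.shape:
            raise ValueError("mean and log-std heads must agree in shape")
        if self.W0.shape[1] != self.W1_mu.shape[0]:
            raise ValueError("W0 output dim must match W1 input dim")
        if self.W1_mu.shape[1] % 2 != 0:
            raise ValueError("latent dimension d must be even")

    @property
    def latent_dim(self) -> int:
        return self.W1_mu.shape[1]


@dataclass
class EncoderOutput:
    """Per-node Gaussian posterior parameters q(z_i) = N(mu_i, diag(sigma_i^2))."""

    mu: np.ndarray
    log_sigma: np.ndarray

    def __post_init__(self) -> None:
        if self.mu.shape != self.log_sigma.shape:
            raise ValueError("mu and log_sigma shapes differ")
        if not (np.all(np.isfinite(self.mu)) and np.all(np.isfinite(self.log_sigma))):
            raise ValueError("non-finite encoder output")


@dataclass
class ExpressionDecoderParams:
    """Two-layer dense decoder: ReLU hidden layer, linear output."""

    V0: np.ndarray
    b0: np.ndarray
    V1: np.ndarray
    b1: np.ndarray


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Out-degree row normalisation D_out^{-1}(A + I).

    The self-loop guarantees out-degree >= 1, so every row sums to exactly 1.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    AI = A + np.eye(A.shape[0])
    return AI / AI.sum(axis=1, keepdims=True)


def encode(A_norm: np.ndarray, features: np.ndarray, params: EncoderParams) -> EncoderOutput:
    """mu = A_n ReLU(A_n X W0) W1_mu, log_sigma likewise with W1_sigma."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] != A_norm.shape[0]:
        raise ValueError("feature rows must align with adjacency nodes")
    hidden = relu(A_norm @ features @ params.W0)
    G = A_norm @ hidden
    return EncoderOutput(mu=G @ params.W1_mu, log_sigma=G @ params.W1_sigma)


def sample_latent(
    enc: EncoderOutput,
    seed: int | np.random.Generator | None = None,
    eval_mode: bool = False,
) -> np.ndarray:
    """Reparameterised draw Z = mu + exp(log_sigma) * eps, eps ~ N(0, I).

    In ``eval_mode`` the posterior mean is returned bit-exactly (no sampling),
    which is how all downstream inference is run.
    """
    if enc.mu.shape[1] % 2 != 0:
        raise ValueError("latent dimension d must be even")
    if eval_mode:
        return enc.mu.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(enc.mu.shape)
    return enc.mu + np.exp(enc.log_sigma) * eps


def _split_source_target(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = Z.shape[1]
    if d % 2 != 0:
        raise ValueError("latent dimension d must be even")
    return Z[:, : d // 2], Z[:, d // 2 :]


def decode_graph(Z: np.ndarray) -> np.ndarray:
    """Directed edge probabilities sigma(<z_i^(s), z_j^(t)>).

    The first d/2 latent dimensions act as the source (sender) code and the
    last d/2 as the target (receiver) code, so the output is generally
    asymmetric.  The diagonal is computed like any entry; callers exclude it.
    """
    Zs, Zt = _split_source_target(np.asarray(Z, dtype=float))
    return sigmoid(Zs @ Zt.T)


def decode_graph_logits(Z: np.ndarray) -> np.ndarray:
    Zs, Zt = _split_source_target(np.asarray(Z, dtype=float))
    return Zs @ Zt.T


def decode_expression(Z: np.ndarray, decoder: ExpressionDecoderParams) -> np.ndarray:
    """Per-node expression reconstruction ReLU(Z V0 + b0) V1 + b1.

    For the gene-level autoencoder rows are genes (output m x n); for the
    cell-level autoencoder rows are cells (transpose to genes x cells for
    the canonical orientation).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != decoder.V0.shape[0]:
        raise ValueError("decoder input dim must equal latent dim")
    return relu(Z @ decoder.V0 + decoder.b0) @ decoder.V1 + decoder.b1


def kl_divergence(enc: EncoderOutput) -> float:
    """Per-node mean KL(q(Z) || N(0, I)).

    Sum over nodes and dimensions of 0.5 (mu^2 + sigma^2 - 1 - 2 log sigma),
    divided by the number of nodes so it balances the per-entry-normalised
    reconstruction terms.
    """
    mu, ls = enc.mu, enc.log_sigma
    n = mu.shape[0]
    return float(
        0.5 * np.sum(mu**2 + np.exp(2.0 * ls) - 1.0 - 2.0 * ls) / n
    )
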