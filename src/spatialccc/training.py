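"""Joint training of the two coupled variational graph autoencoders.

The gene-level autoencoder sees the directed ligand->receptor graph with the
genes x cells expression matrix as node features; the cell-level autoencoder
sees the symmetric spatial graph with the transposed expression as features.
Both are optimised jointly on

    L = (-ELBO_g + L_Xg) + (-ELBO_c + L_Xc) + w L_orth

by full-batch Adam.  Gradients are derived analytically for this fixed
architecture (reverse-mode through the two-layer GCN encoder, the
reparameterised sample, the source/target inner-product decoder, the dense
expression decoder and the cross-autoencoder cosine-similarity penalty);
a finite-difference check in the test-suite guards every path.

Graph reconstruction uses the standard sparse-graph class weighting
pos_weight = (N^2 - E)/E and norm = N^2 / (2 (N^2 - E)), computed per graph
unless overridden.  The summed KL enters the objective scaled by 1/N^2
(the convention of standard VGAE implementations), weighted by ``beta``.
Encoder features are standardised per column (scalers are stored on the
trained model and re-applied at inference).  One posterior sample per
autoencoder per epoch; at evaluation time the posterior mean is used
instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .losses import LossBreakdown
from .vgae import EncoderParams, ExpressionDecoderParams, relu, sigmoid

__all__ = ["Hyperparams", "TrainedModel", "train", "save_model", "load_model"]

_LOG_SIGMA_MAX = 10.0


def feature_scaler(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (center, scale) of a node-feature matrix.

    Constant columns keep center 0 and scale 1, so an all-zero feature
    (e.g. a zero-masked gene) stays all-zero after scaling.
    """
    F = np.asarray(F, dtype=float)
    center = F.mean(axis=0)
    scale = F.std(axis=0)
    const = scale < 1e-12
    return np.where(const, 0.0, center), np.where(const, 1.0, scale)


def apply_scaler(F: np.ndarray, scaler: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    center, scale = scaler
    return (np.asarray(F, dtype=float) - center) / scale


@dataclass
class Hyperparams:
    """Training configuration.

    latent_dim must be even (source/target split); defaults are 16 latent
    dimensions, 32 hidden units in both the GCN and the expression decoder,
    learning rate 0.01 for 200 epochs, and unit weights on the KL and
    orthogonal terms.
    """

    latent_dim: int = 16
    hidden_dim: int = 32
    decoder_hidden: int = 32
    epochs: int = 200
    learning_rate: float = 0.01
    beta: float = 1.0
    orth_weight: float = 1.0
    pos_weight: float | None = None  # per-graph auto when None
    norm: float | None = None

    def __post_init__(self) -> None:
        if self.latent_dim % 2 != 0:
            raise ValueError("latent_dim must be even")


@dataclass
class TrainedModel:
    """Fitted weights of both autoencoders plus the training audit trail."""

    gene_encoder: EncoderParams
    gene_decoder: ExpressionDecoderParams
    cell_encoder: EncoderParams
    cell_decoder: ExpressionDecoderParams
    hyperparams: Hyperparams
    loss_history: list[LossBreakdown] = field(default_factory=list)
    seed: int = 0
    #: per-column (center, scale) applied to encoder features at train time;
    #: inference must apply the same transform
    gene_feat_scaler: tuple[np.ndarray, np.ndarray] | None = None
    cell_feat_scaler: tuple[np.ndarray, np.ndarray] | None = None


def _class_weights(A: np.ndarray, hp: Hyperparams) -> tuple[float, float]:
    N2 = A.size
    E = float(A.sum())
    if hp.pos_weight is not None and hp.norm is not None:
        return hp.pos_weight, hp.norm
    if E == 0 or E == N2:
        pw, nm = 1.0, 0.5
    else:
        pw = (N2 - E) / E
        nm = N2 / (2.0 * (N2 - E))
    return (hp.pos_weight if hp.pos_weight is not None else pw,
            hp.norm if hp.norm is not None else nm)


class JointTrainer:
    """Forward/backward machinery shared by ``train`` and the tests."""

    def __init__(self, X: np.ndarray, A_c: np.ndarray, A_g: np.ndarray,
                 hp: Hyperparams | None = None):
        from .vgae import normalize_adjacency

        self.hp = hp or Hyperparams()
        self.X = np.asarray(X, dtype=float)
        self.A_c = np.asarray(A_c, dtype=float)
        self.A_g = np.asarray(A_g, dtype=float)
        m, n = self.X.shape
        if self.A_c.shape != (n, n):
            raise ValueError("cell adjacency must be n x n")
        if self.A_g.shape != (m, m):
            raise ValueError("gene adjacency must be m x m")
        self.m, self.n = m, n
        self.An_g = normalize_adjacency(self.A_g)
        self.An_c = normalize_adjacency(self.A_c)
        # encoder features are standardised per column so the GCN hidden
        # layer sees signed, unit-scale inputs (all-positive features let a
        # uniform negative drift kill every ReLU unit irrecoverably);
        # reconstruction targets stay on the original scale
        self.scaler_g = feature_scaler(self.X)
        self.scaler_c = feature_scaler(self.X.T)
        self.feats_g = apply_scaler(self.X, self.scaler_g)
        self.feats_c = apply_scaler(self.X.T, self.scaler_c)
        self.pw_g, self.norm_g = _class_weights(self.A_g, self.hp)
        self.pw_c, self.norm_c = _class_weights(self.A_c, self.hp)

    # -- parameters ---------------------------------------------------------

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        hp = self.hp

        def glorot(fi, fo):
            lim = np.sqrt(6.0 / (fi + fo))
            return rng.uniform(-lim, lim, (fi, fo))

        params = {}
        for side, F, out in (("g", self.n, self.n), ("c", self.m, self.m)):
            params[f"{side}_W0"] = glorot(F, hp.hidden_dim)
            params[f"{side}_W1m"] = glorot(hp.hidden_dim, hp.latent_dim)
            params[f"{side}_W1s"] = glorot(hp.hidden_dim, hp.latent_dim)
            params[f"{side}_V0"] = glorot(hp.latent_dim, hp.decoder_hidden)
            # small positive bias keeps decoder ReLU units alive at init
            params[f"{side}_b0"] = np.full(hp.decoder_hidden, 0.01)
            params[f"{side}_V1"] = glorot(hp.decoder_hidden, out)
            # nonzero output bias keeps reconstructed profiles off the
            # zero-norm point where the cosine penalty is non-differentiable
            params[f"{side}_b1"] = np.full(out, 0.01)
        return params

    # -- forward ------------------------------------------------------------

    def _forward_ae(self, params, side, An, feats, A, eps, pw, nm):
        p = {k[2:]: v for k, v in params.items() if k.startswith(side)}
        M = An @ feats
        Hpre = M @ p["W0"]
        H = relu(Hpre)
        G = An @ H
        mu = G @ p["W1m"]
        # clamp log-sigma so exp() cannot overflow early in training
        ls_raw = G @ p["W1s"]
        ls = np.clip(ls_raw, -_LOG_SIGMA_MAX, _LOG_SIGMA_MAX)
        sigma = np.exp(ls)
        Z = mu + sigma * eps if eps is not None else mu
        d2 = Z.shape[1] // 2
        Zs, Zt = Z[:, :d2], Z[:, d2:]
        logits = Zs @ Zt.T
        P = sigmoid(logits)
        # weighted BCE with logits: softplus keeps it stable for any logit
        sp_pos = np.logaddexp(0.0, -logits)   # -log sigmoid(x)
        sp_neg = np.logaddexp(0.0, logits)    # -log(1 - sigmoid(x))
        graph = float(nm * np.mean(pw * A * sp_pos + (1.0 - A) * sp_neg))
        N = Z.shape[0]
        # summed KL scaled by 1/N^2 (per-node mean averaged over nodes again),
        # the scaling standard VGAE implementations use; a stronger prior pull
        # collapses the posterior mean under adaptive gradient normalisation
        kl = float(0.5 * np.sum(mu**2 + sigma**2 - 1.0 - 2.0 * ls) / (N * N))
        Dpre = Z @ p["V0"] + p["b0"]
        Dh = relu(Dpre)
        Xhat = Dh @ p["V1"] + p["b1"]
        cache = dict(
            side=side, p=p, An=An, A=A, eps=eps, pw=pw, nm=nm,
            M=M, Hpre=Hpre, G=G, mu=mu, ls=ls, sigma=sigma, Z=Z,
            ls_active=np.abs(ls_raw) < _LOG_SIGMA_MAX,
            P=P, Dpre=Dpre, Dh=Dh, Xhat=Xhat,
        )
        return graph, kl, cache

    def forward(self, params, eps_g=None, eps_c=None):
        """One full evaluation of the objective; returns (breakdown, caches)."""
        hp = self.hp
        graph_g, kl_g, cg = self._forward_ae(
            params, "g_", self.An_g, self.feats_g, self.A_g, eps_g,
            self.pw_g, self.norm_g)
        graph_c, kl_c, cc = self._forward_ae(
            params, "c_", self.An_c, self.feats_c, self.A_c, eps_c,
            self.pw_c, self.norm_c)
        Xhat_g = cg["Xhat"]          # m x n
        Xhat_c = cc["Xhat"].T        # to genes x cells
        expr_g = float(np.mean((self.X - Xhat_g) ** 2))
        expr_c = float(np.mean((self.X - Xhat_c) ** 2))
        # cross-autoencoder cosine similarity over cells
        nu = np.linalg.norm(Xhat_c, axis=0)
        nv = np.linalg.norm(Xhat_g, axis=0)
        denom = np.outer(nu, nv)
        with np.errstate(divide="ignore", invalid="ignore"):
            S = (Xhat_c.T @ Xhat_g) / denom
        S[denom == 0] = 0.0
        orth = float(np.mean((S - np.eye(self.n)) ** 2))
        parts = LossBreakdown(
            graph_g=graph_g, kl_g=kl_g, expr_g=expr_g,
            graph_c=graph_c, kl_c=kl_c, expr_c=expr_c,
            orth=orth, beta=hp.beta, orth_weight=hp.orth_weight,
        )
        caches = dict(g=cg, c=cc, S=S, nu=nu, nv=nv,
                      Xhat_c=Xhat_c, Xhat_g=Xhat_g)
        return parts, caches

    def loss(self, params, eps_g=None, eps_c=None) -> float:
        return self.forward(params, eps_g, eps_c)[0].total

    # -- backward -----------------------------------------------------------

    def _backward_ae(self, cache, target, dXhat_extra):
        """Gradients for one autoencoder given the extra dL/dXhat term."""
        p = cache["p"]
        A, An = cache["A"], cache["An"]
        pw, nm = cache["pw"], cache["nm"]
        Z, mu, ls, sigma = cache["Z"], cache["mu"], cache["ls"], cache["sigma"]
        N = Z.shape[0]
        beta = self.hp.beta
        # expression head
        dXhat = 2.0 * (cache["Xhat"] - target) / target.size + dXhat_extra
        dV1 = cache["Dh"].T @ dXhat
        db1 = dXhat.sum(axis=0)
        dDh = dXhat @ p["V1"].T
        dDpre = dDh * (cache["Dpre"] > 0)
        dV0 = Z.T @ dDpre
        db0 = dDpre.sum(axis=0)
        dZ = dDpre @ p["V0"].T
        # graph head
        dlogits = (nm / A.size) * (pw * A * (cache["P"] - 1.0)
                                   + (1.0 - A) * cache["P"])
        d2 = Z.shape[1] // 2
        Zs, Zt = Z[:, :d2], Z[:, d2:]
        dZ[:, :d2] += dlogits @ Zt
        dZ[:, d2:] += dlogits.T @ Zs
        # posterior parameters (KL is sum/N^2, weighted by beta)
        dmu = dZ + beta * mu / (N * N)
        dls = beta * (sigma**2 - 1.0) / (N * N)
        if cache["eps"] is not None:
            dls = dls + dZ * cache["eps"] * sigma
        dls = dls * cache["ls_active"]  # clamped entries carry no gradient
        # encoder
        G = cache["G"]
        dW1m = G.T @ dmu
        dW1s = G.T @ dls
        dG = dmu @ p["W1m"].T + dls @ p["W1s"].T
        dH = An.T @ dG
        dHpre = dH * (cache["Hpre"] > 0)
        dW0 = cache["M"].T @ dHpre
        side = cache["side"]
        return {
            f"{side}W0": dW0, f"{side}W1m": dW1m, f"{side}W1s": dW1s,
            f"{side}V0": dV0, f"{side}b0": db0, f"{side}V1": dV1,
            f"{side}b1": db1,
        }

    def backward(self, caches) -> dict[str, np.ndarray]:
        n = self.n
        S, nu, nv = caches["S"], caches["nu"], caches["nv"]
        U, V = caches["Xhat_c"], caches["Xhat_g"]  # both genes x cells
        dS = self.hp.orth_weight * 2.0 * (S - np.eye(n)) / (n * n)
        with np.errstate(divide="ignore", invalid="ignore"):
            W = dS / np.outer(nu, nv)
        W[np.outer(nu, nv) == 0] = 0.0
        # d cos(u_i, v_j)/du_i = v_j/(|u||v|) - S_ij u_i/|u|^2 (zero-norm: 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ru = np.where(nu > 0, ((dS * S).sum(axis=1)) / nu**2, 0.0)
            rv = np.where(nv > 0, ((dS * S).sum(axis=0)) / nv**2, 0.0)
        dU = V @ W.T - U * ru[None, :]
        dV = U @ W - V * rv[None, :]
        grads = self._backward_ae(caches["g"], self.X, dV)
        grads.update(self._backward_ae(caches["c"], self.X.T, dU.T))
        return grads


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _check_finite(parts: LossBreakdown) -> None:
    for name, value in parts.as_dict().items():
        if not np.isfinite(value):
            raise RuntimeError(
                f"training diverged: loss component {name!r} is non-finite"
            )


def train(expr, A_c, A_g, hyperparams: Hyperparams | None = None,
          seed: int = 0) -> TrainedModel:
    """Jointly fit both autoencoders; deterministic given the seed.

    ``expr`` is an ExpressionMatrix (or genes x cells array); ``A_c`` and
    ``A_g`` are SpatialGraph / GeneGraph (or plain adjacency arrays).
    """
    X = getattr(expr, "values", expr)
    Ac = getattr(A_c, "adjacency", A_c)
    Ag = getattr(A_g, "adjacency", A_g)
    hp = hyperparams or Hyperparams()
    trainer = JointTrainer(X, Ac, Ag, hp)
    ss = np.random.SeedSequence(seed)
    init_rng, eps_rng_g, eps_rng_c = (np.random.default_rng(s)
                                      for s in ss.spawn(3))
    params = trainer.init_params(init_rng)
    opt = _Adam(params, hp.learning_rate)
    history: list[LossBreakdown] = []
    for _ in range(hp.epochs):
        eps_g = eps_rng_g.standard_normal((trainer.m, hp.latent_dim))
        eps_c = eps_rng_c.standard_normal((trainer.n, hp.latent_dim))
        parts, caches = trainer.forward(params, eps_g, eps_c)
        _check_finite(parts)
        history.append(parts)
        grads = trainer.backward(caches)
        opt.step(params, grads)
    return TrainedModel(
        gene_encoder=EncoderParams(params["g_W0"], params["g_W1m"], params["g_W1s"]),
        gene_decoder=ExpressionDecoderParams(params["g_V0"], params["g_b0"],
                                             params["g_V1"], params["g_b1"]),
        cell_encoder=EncoderParams(params["c_W0"], params["c_W1m"], params["c_W1s"]),
        cell_decoder=ExpressionDecoderParams(params["c_V0"], params["c_b0"],
                                             params["c_V1"], params["c_b1"]),
        hyperparams=hp,
        loss_history=history,
        seed=seed,
        gene_feat_scaler=trainer.scaler_g,
        cell_feat_scaler=trainer.scaler_c,
    )


def save_model(model: TrainedModel, path: str) -> None:
    """Serialise weights as a flat named-array archive (.npz)."""
    arrays = {
        "g_W0": model.gene_encoder.W0,
        "g_W1m": model.gene_encoder.W1_mu,
        "g_W1s": model.gene_encoder.W1_sigma,
        "g_V0": model.gene_decoder.V0, "g_b0": model.gene_decoder.b0,
        "g_V1": model.gene_decoder.V1, "g_b1": model.gene_decoder.b1,
        "c_W0": model.cell_encoder.W0,
        "c_W1m": model.cell_encoder.W1_mu,
        "c_W1s": model.cell_encoder.W1_sigma,
        "c_V0": model.cell_decoder.V0, "c_b0": model.cell_decoder.b0,
        "c_V1": model.cell_decoder.V1, "c_b1": model.cell_decoder.b1,
    }
    if model.gene_feat_scaler is not None:
        arrays["g_feat_center"], arrays["g_feat_scale"] = model.gene_feat_scaler
    if model.cell_feat_scaler is not None:
        arrays["c_feat_center"], arrays["c_feat_scale"] = model.cell_feat_scaler
    meta = dict(asdict(model.hyperparams), seed=model.seed)
    np.savez(path, _meta=np.array(json.dumps(meta)), **arrays)


def load_model(path: str) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["_meta"]))
        seed = meta.pop("seed", 0)
        hp = Hyperparams(**meta)
        return TrainedModel(
            gene_encoder=EncoderParams(z["g_W0"], z["g_W1m"], z["g_W1s"]),
            gene_decoder=ExpressionDecoderParams(z["g_V0"], z["g_b0"],
                                                 z["g_V1"], z["g_b1"]),
            cell_encoder=EncoderParams(z["c_W0"], z["c_W1m"], z["c_W1s"]),
            cell_decoder=ExpressionDecoderParams(z["c_V0"], z["c_b0"],
                                                 z["c_V1"], z["c_b1"]),
            hyperparams=hp,
            loss_history=[],
            seed=seed,
            gene_feat_scaler=((z["g_feat_center"], z["g_feat_scale"])
                              if "g_feat_center" in z else None),
            cell_feat_scaler=((z["c_feat_center"], z["c_feat_scale"])
                              if "c_feat_center" in z else None),
        )
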