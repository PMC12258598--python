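"""From trained weights to communication calls.

The directed weighted cell-cell network is the decoded edge-probability
matrix at the posterior mean; cell-type-level strengths are means of those
probabilities over ordered cell pairs, with significance from whole-vector
label permutations; ligand-receptor pairs are ranked by the edge reduction
ratio (the fraction of predicted sender->receiver communications lost when
one gene-graph edge is removed and the model retrained under identical
seeds); and spectral clustering of the symmetrised network recovers
communication-driven cell states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering

from .graphs import GeneGraph, SpatialGraph
from .io import CellTypeLabels, ExpressionMatrix
from .training import Hyperparams, TrainedModel, train
from .vgae import decode_graph, encode, normalize_adjacency

__all__ = [
    "CCCNetwork",
    "CellTypeCommMatrix",
    "predict_ccc_network",
    "aggregate_by_cell_type",
    "permutation_test",
    "lr_pair_impact",
    "lr_impact_table",
    "rank_lr_pairs",
    "spectral_clusters",
]


@dataclass
class CCCNetwork:
    """Directed edge probabilities between cells plus a binarisation cutoff."""

    probs: np.ndarray
    cutoff: float = 0.5
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.probs, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("probs must be square")
        if np.any(P < 0) or np.any(P > 1):
            raise ValueError("probs outside [0, 1]")
        self.probs = P

    @property
    def n_cells(self) -> int:
        return self.probs.shape[0]

    @property
    def binary(self) -> np.ndarray:
        """Boolean matrix of called edges; self-communication excluded."""
        B = self.probs >= self.cutoff
        np.fill_diagonal(B, False)
        return B

    @property
    def binary_edges(self) -> set[tuple[int, int]]:
        ii, jj = np.nonzero(self.binary)
        return set(zip(ii.tolist(), jj.tolist()))


@dataclass
class CellTypeCommMatrix:
    """Sender-type x receiver-type strengths with optional permutation p-values."""

    strength: pd.DataFrame
    pvalue: pd.DataFrame | None = None
    n_perm: int = 0
    #: (k, l) type pairs whose strength is a mean over zero pairs (flagged 0)
    empty_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def type_names(self) -> list[str]:
        return list(self.strength.index)


def predict_ccc_network(
    model: TrainedModel,
    expr: ExpressionMatrix,
    A_c: SpatialGraph,
    cutoff: float = 0.5,
) -> CCCNetwork:
    """Decode the communication network at Z = mu (no sampling)."""
    X = getattr(expr, "values", expr)
    Ac = getattr(A_c, "adjacency", A_c)
    X = np.asarray(X, dtype=float)
    if model.cell_encoder.W0.shape[0] != X.shape[0]:
        raise ValueError(
            "expression gene dimension does not match the trained checkpoint"
        )
    An = normalize_adjacency(Ac)
    feats = X.T
    if model.cell_feat_scaler is not None:
        from .training import apply_scaler

        feats = apply_scaler(feats, model.cell_feat_scaler)
    enc = encode(An, feats, model.cell_encoder)
    probs = decode_graph(enc.mu)
    cell_ids = getattr(expr, "cell_ids", None)
    return CCCNetwork(probs, cutoff=cutoff,
                      cell_ids=list(cell_ids) if cell_ids else None)


def _strengths(P: np.ndarray, codes: np.ndarray, K: int) -> np.ndarray:
    """Mean probability over ordered (type k -> type l) cell pairs, i != j."""
    M = np.zeros((P.shape[0], K))
    M[np.arange(P.shape[0]), codes] = 1.0
    sums = M.T @ P @ M
    counts = np.outer(M.sum(0), M.sum(0))
    diag_p = np.diag(P)
    for k in range(K):
        in_k = codes == k
        sums[k, k] -= diag_p[in_k].sum()
        counts[k, k] -= in_k.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        out = sums / counts
    out[counts == 0] = 0.0  # single-cell types: within-type mean over 0 pairs
    return out


def aggregate_by_cell_type(
    net: CCCNetwork, labels: CellTypeLabels
) -> CellTypeCommMatrix:
    """Average communication weight from every sender type to every receiver type."""
    lab = np.asarray(labels.labels, dtype=object)
    if lab.size != net.n_cells:
        raise ValueError("labels must cover all cells")
    types = sorted(set(lab.tolist()))
    codes = np.array([types.index(x) for x in lab])
    strength = _strengths(net.probs, codes, len(types))
    counts = np.bincount(codes, minlength=len(types))
    empty = [(t, t) for t, c in zip(types, counts) if c == 1]
    return CellTypeCommMatrix(
        strength=pd.DataFrame(strength, index=types, columns=types),
        empty_pairs=empty,
    )


def permutation_test(
    net: CCCNetwork,
    labels: CellTypeLabels,
    n_perm: int = 1000,
    seed: int = 0,
) -> CellTypeCommMatrix:
    """Permutation p-values for cell-type communication strengths.

    The whole label vector is permuted uniformly at random per replicate and
    p = (1 + #{permuted strength >= observed}) / (1 + n_perm), so p-values
    lie in (0, 1] and are never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    agg = aggregate_by_cell_type(net, labels)
    types = agg.type_names
    K = len(types)
    lab = np.asarray(labels.labels, dtype=object)
    codes = np.array([types.index(x) for x in lab])
    obs = agg.strength.to_numpy()
    rng = np.random.default_rng(seed)
    exceed = np.zeros((K, K), dtype=int)
    for _ in range(n_perm):
        perm_codes = rng.permutation(codes)
        exceed += _strengths(net.probs, perm_codes, K) >= obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return CellTypeCommMatrix(
        strength=agg.strength,
        pvalue=pd.DataFrame(pvals, index=types, columns=types),
        n_perm=n_perm,
        empty_pairs=agg.empty_pairs,
    )


def _count_type_edges(
    net: CCCNetwork, labels: CellTypeLabels, sender: str, receiver: str
) -> int:
    lab = np.asarray(labels.labels, dtype=object)
    B = net.binary
    send = lab == sender
    recv = lab == receiver
    return int(B[np.ix_(send, recv)].sum())


def lr_pair_impact(
    expr: ExpressionMatrix,
    A_c: SpatialGraph,
    A_g: GeneGraph,
    labels: CellTypeLabels,
    lr_edge: tuple[str, str],
    sender: str,
    receiver: str,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
    cutoff: float = 0.5,
    reference: CCCNetwork | None = None,
) -> float:
    """Edge reduction ratio of one ligand->receptor gene edge.

    The model is retrained with the edge removed from the gene graph, under
    the same seed and hyperparameters as the reference run, and the ratio
    max(0, (E_full - E_perturbed) / E_full) of lost sender->receiver calls
    is returned (0 when the reference makes no such calls).  ``reference``
    lets callers reuse a precomputed full-graph network across many edges.
    """
    ligand, receptor = lr_edge
    A_g_pert = A_g.remove_edge(ligand, receptor)  # raises if absent
    if reference is None:
        model_full = train(expr, A_c, A_g, hyperparams, seed=seed)
        reference = predict_ccc_network(model_full, expr, A_c, cutoff=cutoff)
    E_full = _count_type_edges(reference, labels, sender, receiver)
    if E_full == 0:
        return 0.0
    model_pert = train(expr, A_c, A_g_pert, hyperparams, seed=seed)
    net_pert = predict_ccc_network(model_pert, expr, A_c, cutoff=cutoff)
    E_pert = _count_type_edges(net_pert, labels, sender, receiver)
    return max(0.0, (E_full - E_pert) / E_full)


def lr_impact_table(
    expr: ExpressionMatrix,
    A_c: SpatialGraph,
    A_g: GeneGraph,
    labels: CellTypeLabels,
    sender: str,
    receiver: str,
    lr_edges: list[tuple[str, str]] | None = None,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Edge reduction ratios for many LR pairs of one (sender, receiver) pair.

    Trains the reference model once, then one perturbed retrain per edge.
    """
    if lr_edges is None:
        lr_edges = A_g.edge_gene_pairs()
    model_full = train(expr, A_c, A_g, hyperparams, seed=seed)
    reference = predict_ccc_network(model_full, expr, A_c, cutoff=cutoff)
    rows = []
    for ligand, receptor in lr_edges:
        ratio = lr_pair_impact(
            expr, A_c, A_g, labels, (ligand, receptor), sender, receiver,
            hyperparams=hyperparams, seed=seed, cutoff=cutoff,
            reference=reference,
        )
        rows.append({
            "ligand": ligand, "receptor": receptor,
            "sender": sender, "receiver": receiver,
            "edge_reduction_ratio": ratio,
        })
    return pd.DataFrame(
        rows, columns=["ligand", "receptor", "sender", "receiver",
                       "edge_reduction_ratio"],
    )


def rank_lr_pairs(impacts: pd.DataFrame, top_k: int = 20) -> pd.DataFrame:
    """Top LR pairs by edge reduction ratio with dense ranks.

    Sorted by ratio descending; ties broken by (ligand, receptor)
    lexicographic order; equal ratios share a rank (dense ranking).
    """
    df = impacts.sort_values(
        ["edge_reduction_ratio", "ligand", "receptor"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    df["rank"] = (
        df["edge_reduction_ratio"].rank(method="dense", ascending=False).astype(int)
    )
    return df.head(min(top_k, len(df)))


def spectral_clusters(net: CCCNetwork, k: int, seed: int = 0) -> np.ndarray:
    """Normalised spectral clustering of the symmetrised affinity (P + P^T)/2.

    Cluster IDs are arbitrary; compare partitions, not labels.  ``k`` must
    satisfy 2 <= k <= n_cells (k == n_cells degenerates to singletons up to
    the solver's behaviour and larger k is an error).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > net.n_cells:
        raise ValueError("k cannot exceed the number of cells")
    affinity = (net.probs + net.probs.T) / 2.0
    sc = SpectralClustering(
        n_clusters=k, affinity="precomputed", random_state=seed,
        assign_labels="kmeans",
    )
    return sc.fit_predict(affinity)
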