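"""Evaluation machinery: ranking metrics, gene sensitivity, robustness.

Average precision and ROC-AUC are implemented exactly (AP by walking the
ranked candidate list with a fixed tie order, AUC in its Mann-Whitney form
with half-credit for ties).  Gene sensitivity measures how much zeroing (or
shuffling) one gene's expression changes the model's ability to recover the
spatial graph, quantified as |delta AP|.  The robustness protocol retrains
the model on spatial graphs with edges randomly removed or fake edges
injected, and scores the perturbed run's probabilities against the
reference run's predictions (or against the removed edges themselves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .graphs import SpatialGraph
from .inference import predict_ccc_network
from .io import ExpressionMatrix
from .training import Hyperparams, TrainedModel, train

__all__ = [
    "average_precision",
    "auc",
    "SensitivityScores",
    "gene_sensitivity",
    "gene_sensitivity_scores",
    "rank_sensitive_genes",
    "RobustnessResult",
    "robustness_remove",
    "robustness_fake",
]


def average_precision(scores, reference) -> float:
    """Area under the precision-recall curve of a ranked candidate list.

    Candidates are ranked by score descending (ties broken by their fixed
    input order, stable sort); AP is the mean of precision-at-rank over the
    positives' ranks, i.e. precision weighted by recall increments.
    """
    scores = np.asarray(scores, dtype=float)
    reference = np.asarray(reference)
    if scores.shape != reference.shape or scores.ndim != 1:
        raise ValueError("scores and reference must be 1-D and aligned")
    n_pos = int(reference.sum())
    if n_pos == 0:
        raise ValueError("no positive candidates in reference")
    order = np.argsort(-scores, kind="stable")
    hits = reference[order].astype(float)
    cum_hits = np.cumsum(hits)
    ranks = np.arange(1, scores.size + 1)
    precision_at = cum_hits / ranks
    return float(np.sum(precision_at * hits) / n_pos)


def auc(scores_pos, scores_neg) -> float:
    """Exact Mann-Whitney AUC: P(pos > neg) + 0.5 P(tie)."""
    scores_pos = np.asarray(scores_pos, dtype=float).ravel()
    scores_neg = np.asarray(scores_neg, dtype=float).ravel()
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("both score sets must be non-empty")
    n_pos, n_neg = scores_pos.size, scores_neg.size
    ranks = rankdata(np.concatenate([scores_pos, scores_neg]))
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# gene sensitivity


@dataclass
class SensitivityScores:
    """Per-gene |delta AP| scores against a common baseline."""

    scores: dict[str, float]
    baseline_ap: float
    perturbation_mode: str = "zero-mask"

    def as_series(self):
        import pandas as pd

        return pd.Series(self.scores, name="sensitivity")


def _offdiag(M: np.ndarray) -> np.ndarray:
    mask = ~np.eye(M.shape[0], dtype=bool)
    return np.asarray(M)[mask]


def _gene_baselines(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Per-gene baseline level used by the zero-mask knockout.

    The training-time feature center when the model carries one (so the
    masked gene's standardised feature is exactly zero), otherwise zero.
    """
    if model.cell_feat_scaler is not None:
        return np.asarray(model.cell_feat_scaler[0], dtype=float)
    return np.zeros(X.shape[0])


def _edge_recovery_ap(model: TrainedModel, X: np.ndarray,
                      A_c: np.ndarray) -> float:
    net = predict_ccc_network(model, X, A_c)
    return average_precision(_offdiag(net.probs), _offdiag(A_c) > 0)


def _perturb_gene(X: np.ndarray, gi: int, mode: str, seed: int,
                  baseline: float = 0.0) -> np.ndarray:
    """Knock out one gene's profile.

    ``zero-mask`` pins the gene at its training-time baseline level across
    all cells, i.e. zeroes its standardised encoder feature and so removes
    its cell-to-cell variation (a gene that is all-zero in the data has
    baseline 0, making the perturbation an exact identity).  ``shuffle``
    permutes the gene's values across cells, preserving its marginal
    distribution while destroying its spatial pattern.
    """
    Xp = X.copy()
    if mode == "zero-mask":
        Xp[gi] = baseline
    elif mode == "shuffle":
        rng = np.random.default_rng(seed)
        Xp[gi] = rng.permutation(Xp[gi])
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")
    return Xp


def gene_sensitivity(
    model: TrainedModel,
    expr: ExpressionMatrix,
    A_c: SpatialGraph,
    gene: str,
    mode: str = "zero-mask",
    seed: int = 0,
) -> float:
    """|AP_perturbed - AP_baseline| for one gene (inference-only perturbation).

    Candidates are all ordered non-diagonal cell pairs scored by the decoded
    probabilities; positives are the spatial-graph edges.  The trained model
    is reused: only inference is rerun on the perturbed expression.
    """
    X = np.asarray(getattr(expr, "values", expr), dtype=float)
    Ac = np.asarray(getattr(A_c, "adjacency", A_c))
    gene_ids = list(getattr(expr, "gene_ids", range(X.shape[0])))
    if gene not in gene_ids:
        raise KeyError(f"unknown gene {gene!r}")
    gi = gene_ids.index(gene)
    baselines = _gene_baselines(model, X)
    base = _edge_recovery_ap(model, X, Ac)
    pert = _edge_recovery_ap(
        model, _perturb_gene(X, gi, mode, seed, baselines[gi]), Ac
    )
    return abs(pert - base)


def gene_sensitivity_scores(
    model: TrainedModel,
    expr: ExpressionMatrix,
    A_c: SpatialGraph,
    genes: list[str] | None = None,
    mode: str = "zero-mask",
    seed: int = 0,
) -> SensitivityScores:
    """Sensitivity scores for many genes, computing the baseline AP once."""
    X = np.asarray(getattr(expr, "values", expr), dtype=float)
    Ac = np.asarray(getattr(A_c, "adjacency", A_c))
    gene_ids = list(getattr(expr, "gene_ids", [str(i) for i in range(X.shape[0])]))
    if genes is None:
        genes = gene_ids
    baselines = _gene_baselines(model, X)
    base = _edge_recovery_ap(model, X, Ac)
    scores: dict[str, float] = {}
    for g in genes:
        if g not in gene_ids:
            raise KeyError(f"unknown gene {g!r}")
        gi = gene_ids.index(g)
        ap = _edge_recovery_ap(
            model, _perturb_gene(X, gi, mode, seed, baselines[gi]), Ac
        )
        scores[g] = abs(ap - base)
    return SensitivityScores(scores=scores, baseline_ap=base,
                             perturbation_mode=mode)


def rank_sensitive_genes(scores: SensitivityScores, top_fraction: float) -> list[str]:
    """Top ceil(fraction * m) genes by sensitivity, ties lexicographic."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    items = sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    k = math.ceil(top_fraction * len(items))
    return [g for g, _ in items[:k]]


# ---------------------------------------------------------------------------
# robustness protocol


@dataclass
class RobustnessResult:
    """AUC matrix (levels x replicates) of one perturbation scenario."""

    scenario: str
    levels: list[float]
    auc: np.ndarray
    n_replicates: int
    seeds: list[int] = field(default_factory=list)

    def median_by_level(self) -> np.ndarray:
        return np.median(self.auc, axis=1)


def _sample_nonedges(A: np.ndarray, count: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Uniformly sample undirected non-edges (i < j) without replacement."""
    n = A.shape[0]
    iu, ju = np.nonzero(np.triu(~(A > 0), k=1))
    if iu.size < count:
        raise ValueError("insufficient non-edges to sample")
    pick = rng.choice(iu.size, size=count, replace=False)
    return np.column_stack([iu[pick], ju[pick]])


def _prediction_auc(
    probs: np.ndarray,
    pos_pairs: np.ndarray,
    neg_pairs: np.ndarray,
) -> float:
    """AUC of directed probabilities over undirected pair sets (both directions)."""
    def both_dir(pairs):
        return np.concatenate([probs[pairs[:, 0], pairs[:, 1]],
                               probs[pairs[:, 1], pairs[:, 0]]])

    return auc(both_dir(pos_pairs), both_dir(neg_pairs))


def _reference_pred_pairs(net, rng) -> tuple[np.ndarray, np.ndarray]:
    """Reference run's directed predicted edges and an equal sample of
    directed non-predicted ordered pairs (diagonal excluded)."""
    B = net.binary
    pos = np.column_stack(np.nonzero(B))
    if pos.shape[0] == 0:
        raise ValueError("reference run predicts no edges")
    non = ~B
    np.fill_diagonal(non, False)
    ii, jj = np.nonzero(non)
    if ii.size == 0:
        raise ValueError("reference run predicts every pair; no negatives")
    # equal-sized negative sample, capped by the available non-predictions
    pick = rng.choice(ii.size, size=min(pos.shape[0], ii.size), replace=False)
    neg = np.column_stack([ii[pick], jj[pick]])
    return pos, neg


def _run_robustness(
    expr, A_c, A_g, levels, n_reps, hyperparams, base_seed, scenario,
    score_against,
):
    X = getattr(expr, "values", expr)
    Ac = np.asarray(getattr(A_c, "adjacency", A_c), dtype=int)
    hp = hyperparams or Hyperparams()
    ss = np.random.SeedSequence(base_seed)
    train_seed = int(ss.generate_state(1)[0] % (2**31))
    model_ref = train(X, Ac, A_g, hp, seed=train_seed)
    net_ref = predict_ccc_network(model_ref, X, Ac)
    edges = np.column_stack(np.nonzero(np.triu(Ac, k=1)))
    n_edges = edges.shape[0]
    rep_seeds = [int(s.generate_state(1)[0] % (2**31))
                 for s in ss.spawn(len(levels) * n_reps)]
    aucs = np.zeros((len(levels), n_reps))
    idx = 0
    for li, level in enumerate(levels):
        for rep in range(n_reps):
            rng = np.random.default_rng(rep_seeds[idx])
            idx += 1
            A_pert = Ac.copy()
            if scenario == "remove":
                n_del = int(round(level * n_edges))
                if n_del >= n_edges:
                    raise ValueError("ratio leaves zero edges")
                pick = rng.choice(n_edges, size=n_del, replace=False)
                removed = edges[pick]
                A_pert[removed[:, 0], removed[:, 1]] = 0
                A_pert[removed[:, 1], removed[:, 0]] = 0
            else:  # fake
                n_add = int(round(level * n_edges))
                added = (_sample_nonedges(Ac, n_add, rng)
                         if n_add else np.empty((0, 2), dtype=int))
                A_pert[added[:, 0], added[:, 1]] = 1
                A_pert[added[:, 1], added[:, 0]] = 1
            model_p = train(X, A_pert, A_g, hp, seed=train_seed)
            net_p = predict_ccc_network(model_p, X, A_pert)
            if score_against == "removed":
                if scenario != "remove" or removed.shape[0] == 0:
                    raise ValueError(
                        "score_against='removed' needs a nonzero removal ratio"
                    )
                neg = _sample_nonedges(Ac, removed.shape[0], rng)
                aucs[li, rep] = _prediction_auc(net_p.probs, removed, neg)
            else:
                pos, neg = _reference_pred_pairs(net_ref, rng)
                aucs[li, rep] = auc(net_p.probs[pos[:, 0], pos[:, 1]],
                                    net_p.probs[neg[:, 0], neg[:, 1]])
    return RobustnessResult(
        scenario=scenario, levels=[float(x) for x in levels], auc=aucs,
        n_replicates=n_reps, seeds=rep_seeds,
    )


def robustness_remove(
    expr,
    A_c,
    A_g,
    ratios,
    n_reps: int = 30,
    hyperparams: Hyperparams | None = None,
    base_seed: int = 0,
    score_against: str = "predictions",
) -> RobustnessResult:
    """Edge-removal robustness: retrain on subgraphs, score against reference.

    Per replicate a fraction of undirected spatial edges is deleted
    uniformly without replacement, the model retrained (seed pinned to the
    reference run), and the perturbed run's probabilities scored by AUC.
    ``score_against='predictions'`` uses the reference run's predicted edges
    as positives with an equal sample of non-predictions as negatives;
    ``score_against='removed'`` scores recovery of the deleted edges against
    sampled non-edges of the original graph.
    """
    for r in ratios:
        if not 0 <= r < 1:
            raise ValueError("each removal ratio must be in [0, 1)")
    return _run_robustness(expr, A_c, A_g, list(ratios), n_reps, hyperparams,
                           base_seed, "remove", score_against)


def robustness_fake(
    expr,
    A_c,
    A_g,
    multipliers,
    n_reps: int = 30,
    hyperparams: Hyperparams | None = None,
    base_seed: int = 0,
) -> RobustnessResult:
    """Fake-edge robustness: inject multiplier x |edges| false symmetric edges.

    Added edges never duplicate existing edges or the diagonal; the model
    is retrained on the corrupted graph and its probabilities are scored
    against the reference run's predictions.
    """
    for mlt in multipliers:
        if mlt < 0:
            raise ValueError("multipliers must be >= 0")
    return _run_robustness(expr, A_c, A_g, list(multipliers), n_reps,
                           hyperparams, base_seed, "fake", "predictions")
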