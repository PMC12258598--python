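"""Model/Results interface for communication inference.

`CellCommunicationModel` bundles the data (expression, spatial coordinates
or graph, ligand-receptor database or gene graph, optional cell-type
labels) and the training configuration; `fit()` runs the coupled
variational graph autoencoders and returns a `CellCommunicationResults`
carrying the trained weights, the loss history and every downstream
analysis as a method.

    >>> model = CellCommunicationModel(expr, coords, labels=labels, lr_db=db)
    >>> res = model.fit(seed=0)
    >>> net = res.predict_network()
    >>> res.cell_type_communication(n_perm=1000, seed=1).pvalue
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import evaluation, inference
from .graphs import (
    GeneGraph,
    SpatialGraph,
    build_gene_graph,
    build_spatial_graph,
    select_distance_threshold,
)
from .io import (
    CellTypeLabels,
    ExpressionMatrix,
    LigandReceptorDatabase,
    SpatialCoordinates,
)
from .training import Hyperparams, TrainedModel, train

__all__ = ["CellCommunicationModel", "CellCommunicationResults"]


class CellCommunicationModel:
    """Directed cell-cell communication model over a spatial tissue graph.

    Parameters
    ----------
    expression
        Genes x cells ExpressionMatrix.
    coords
        Spatial coordinates (same cell order as the expression columns).
        May be omitted when ``spatial_graph`` is given directly.
    labels
        Optional cell-type labels; required for type-level analyses.
    lr_db
        Ligand-receptor database; may be omitted when ``gene_graph`` is
        given directly.
    distance_threshold
        Spatial radius, or "auto" for the neighbour-count heuristic (the
        smallest candidate radius under which >80% of cells have at least
        three neighbours).
    log_transform
        Model the log1p-transformed expression (default True, the field's
        standard variance-stabilising choice for count-like data); the
        expression-gating of the gene graph always uses the raw values.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        coords: SpatialCoordinates | None = None,
        labels: CellTypeLabels | None = None,
        lr_db: LigandReceptorDatabase | None = None,
        distance_threshold: float | str = "auto",
        min_cells_expressing: int = 1,
        spatial_graph: SpatialGraph | None = None,
        gene_graph: GeneGraph | None = None,
        hyperparams: Hyperparams | None = None,
        log_transform: bool = True,
    ):
        self.expression = expression
        self.log_transform = log_transform
        self.model_expression = (
            ExpressionMatrix(np.log1p(expression.values),
                             list(expression.gene_ids),
                             list(expression.cell_ids))
            if log_transform else expression
        )
        self.coords = coords
        self.labels = labels
        self.hyperparams = hyperparams or Hyperparams()
        if labels is not None and len(labels.labels) != expression.n_cells:
            raise ValueError("labels must cover every cell")
        if spatial_graph is None:
            if coords is None:
                raise ValueError("need either coords or spatial_graph")
            if coords.n_cells != expression.n_cells:
                raise ValueError("coordinates must cover every cell")
            if distance_threshold == "auto":
                distance_threshold = select_distance_threshold(coords)
            spatial_graph = build_spatial_graph(coords, float(distance_threshold))
        self.spatial_graph = spatial_graph
        if gene_graph is None:
            if lr_db is None:
                raise ValueError("need either lr_db or gene_graph")
            gene_graph = build_gene_graph(
                lr_db, expression, min_cells_expressing=min_cells_expressing
            )
        self.gene_graph = gene_graph

    @classmethod
    def from_synthetic(cls, dataset, distance_threshold: float | str = "auto",
                       **kwargs) -> "CellCommunicationModel":
        """Build a model directly from a synthetic dataset bundle."""
        return cls(
            dataset.expression,
            coords=dataset.coords,
            labels=dataset.labels,
            lr_db=dataset.lr_db,
            distance_threshold=distance_threshold,
            **kwargs,
        )

    def fit(self, seed: int = 0, epochs: int | None = None) -> "CellCommunicationResults":
        """Train both autoencoders jointly; deterministic given ``seed``."""
        hp = self.hyperparams
        if epochs is not None:
            hp = Hyperparams(**{**hp.__dict__, "epochs": epochs})
        trained = train(self.model_expression, self.spatial_graph, self.gene_graph,
                        hp, seed=seed)
        return CellCommunicationResults(self, trained)


class CellCommunicationResults:
    """Fitted communication model: weights, diagnostics, downstream analyses."""

    def __init__(self, model: CellCommunicationModel, trained: TrainedModel):
        self.model = model
        self.trained = trained

    @property
    def loss_history(self):
        return self.trained.loss_history

    def loss_frame(self) -> pd.DataFrame:
        """Per-epoch loss components as a DataFrame."""
        return pd.DataFrame([p.as_dict() for p in self.loss_history])

    # -- downstream ---------------------------------------------------------

    def predict_network(self, cutoff: float = 0.5) -> inference.CCCNetwork:
        """Directed edge probabilities at the posterior mean."""
        return inference.predict_ccc_network(
            self.trained, self.model.model_expression, self.model.spatial_graph,
            cutoff=cutoff,
        )

    def _require_labels(self) -> CellTypeLabels:
        if self.model.labels is None:
            raise ValueError("cell-type labels are required for this analysis")
        return self.model.labels

    def cell_type_communication(
        self, n_perm: int = 1000, seed: int = 0, cutoff: float = 0.5
    ) -> inference.CellTypeCommMatrix:
        """Type-level strengths with label-permutation p-values."""
        net = self.predict_network(cutoff=cutoff)
        return inference.permutation_test(
            net, self._require_labels(), n_perm=n_perm, seed=seed
        )

    def lr_impact(
        self, sender: str, receiver: str,
        lr_edges: list[tuple[str, str]] | None = None,
        top_k: int | None = None, cutoff: float = 0.5,
    ) -> pd.DataFrame:
        """Edge reduction ratios (one retrain per LR edge, seeds pinned)."""
        table = inference.lr_impact_table(
            self.model.model_expression, self.model.spatial_graph,
            self.model.gene_graph, self._require_labels(),
            sender, receiver, lr_edges=lr_edges,
            hyperparams=self.trained.hyperparams, seed=self.trained.seed,
            cutoff=cutoff,
        )
        if top_k is not None:
            table = inference.rank_lr_pairs(table, top_k=top_k)
        return table

    def gene_sensitivity(
        self, genes: list[str] | None = None, mode: str = "zero-mask",
        seed: int = 0,
    ) -> evaluation.SensitivityScores:
        """|delta AP| of spatial-edge recovery per zero-masked/shuffled gene."""
        return evaluation.gene_sensitivity_scores(
            self.trained, self.model.model_expression, self.model.spatial_graph,
            genes=genes, mode=mode, seed=seed,
        )

    def spectral_clusters(self, k: int, seed: int = 0,
                          cutoff: float = 0.5) -> np.ndarray:
        """Spectral clustering of the symmetrised communication network."""
        return inference.spectral_clusters(
            self.predict_network(cutoff=cutoff), k, seed=seed
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary."""
        hp = self.trained.hyperparams
        first, last = self.loss_history[0], self.loss_history[-1]
        sg, gg = self.model.spatial_graph, self.model.gene_graph
        lines = [
            "Cell-cell communication model (coupled variational graph autoencoders)",
            "=" * 72,
            f"cells: {self.model.expression.n_cells}    "
            f"genes: {self.model.expression.n_genes}    "
            f"spatial edges: {sg.n_edges} (threshold {sg.threshold_used:.4g})    "
            f"LR edges: {gg.n_edges}",
            f"latent dim: {hp.latent_dim}    hidden dim: {hp.hidden_dim}    "
            f"epochs: {hp.epochs}    lr: {hp.learning_rate}    "
            f"seed: {self.trained.seed}",
            "-" * 72,
            f"{'component':<14}{'initial':>12}{'final':>12}",
        ]
        for name in ("graph_g", "kl_g", "expr_g", "graph_c", "kl_c",
                     "expr_c", "orth", "total"):
            lines.append(
                f"{name:<14}{first.as_dict()[name]:>12.4f}"
                f"{last.as_dict()[name]:>12.4f}"
            )
        if self.model.labels is not None:
            net = self.predict_network()
            agg = inference.aggregate_by_cell_type(net, self.model.labels)
            st = agg.strength.stack().sort_values(ascending=False)
            lines.append("-" * 72)
            lines.append("strongest type-level communications (sender -> receiver):")
            for (snd, rcv), val in st.head(5).items():
                lines.append(f"  {snd} -> {rcv}: {val:.4f}")
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Loss-component trajectories over epochs."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.loss_frame()
        for col in df.columns:
            ax.plot(df.index, df[col], label=col)
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend(fontsize="small")
        return ax
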