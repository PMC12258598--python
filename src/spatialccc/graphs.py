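"""Spatial cell/spot graph and directed ligand-receptor gene graph.

The spatial graph connects cells whose Euclidean distance is strictly below
a threshold; the threshold can be chosen by the neighbour-count heuristic
(the smallest candidate under which more than 80% of cells have at least
three neighbours, reflecting that most cells in a 2-D tissue touch several
adjacent cells).  The gene graph is a directed ligand -> receptor adjacency
obtained by expanding database records (including multi-subunit complexes)
to gene-level ordered pairs, gated on the genes being expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .io import ExpressionMatrix, LigandReceptorDatabase, SpatialCoordinates

__all__ = [
    "SpatialGraph",
    "GeneGraph",
    "build_spatial_graph",
    "select_distance_threshold",
    "default_threshold_candidates",
    "build_gene_graph",
    "count_edges_by_distance",
]


@dataclass
class SpatialGraph:
    """Binary symmetric spatial adjacency with the threshold that built it."""

    adjacency: np.ndarray
    threshold_used: float
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        A = self.adjacency
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return int(self.adjacency.sum()) // 2

    def edge_pairs(self) -> np.ndarray:
        """Undirected edges as an (E, 2) array of index pairs with i < j."""
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        return np.column_stack([iu, ju])


@dataclass
class GeneGraph:
    """Directed ligand(row) -> receptor(column) gene adjacency."""

    adjacency: np.ndarray
    gene_ids: list[str]
    #: (ligand index, receptor index) -> list of source record indices
    pair_index: dict[tuple[int, int], list[int]] = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        self.adjacency = A

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def edge_gene_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.gene_ids[i], self.gene_ids[j])
            for i, j in sorted(self.pair_index)
        ]

    def remove_edge(self, ligand: str, receptor: str) -> "GeneGraph":
        """Return a copy with one ligand->receptor edge removed."""
        gi = {g: k for k, g in enumerate(self.gene_ids)}
        if ligand not in gi or receptor not in gi:
            raise KeyError(f"edge {ligand}->{receptor} not in gene graph")
        i, j = gi[ligand], gi[receptor]
        if not self.adjacency[i, j]:
            raise KeyError(f"edge {ligand}->{receptor} not in gene graph")
        A = self.adjacency.copy()
        A[i, j] = 0
        pair_index = {k: v for k, v in self.pair_index.items() if k != (i, j)}
        return GeneGraph(A, list(self.gene_ids), pair_index, dict(self.report))


def build_spatial_graph(
    coords: SpatialCoordinates, threshold: float
) -> SpatialGraph:
    """Connect cells with pairwise Euclidean distance strictly below ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if coords.n_cells < 2:
        raise ValueError("need at least two cells")
    D = squareform(pdist(coords.xy))
    A = (D < threshold).astype(np.int8)
    np.fill_diagonal(A, 0)
    return SpatialGraph(A, float(threshold), list(coords.cell_ids))


def default_threshold_candidates(
    coords: SpatialCoordinates, n_candidates: int = 20
) -> np.ndarray:
    """Log-spaced grid between the 1st and 50th percentile of nonzero distances."""
    d = pdist(coords.xy)
    d = d[d > 0]
    lo, hi = np.percentile(d, [1, 50])
    lo = max(lo, 1e-12)
    return np.geomspace(lo, hi, n_candidates)


def select_distance_threshold(
    coords: SpatialCoordinates,
    min_neighbors: int = 3,
    fraction: float = 0.8,
    candidates=None,
) -> float:
    """Pick the smallest candidate threshold giving most cells enough neighbours.

    Returns the smallest candidate ``t`` such that strictly more than
    ``fraction`` of cells have at least ``min_neighbors`` neighbours at
    distance < t.  If no candidate qualifies the largest one is returned
    with a warning.
    """
    if candidates is None:
        candidates = default_threshold_candidates(coords)
    candidates = np.asarray(list(candidates), dtype=float)
    if candidates.size == 0:
        raise ValueError("empty candidate list")
    D = squareform(pdist(coords.xy))
    np.fill_diagonal(D, np.inf)
    for t in candidates:
        degrees = (D < t).sum(axis=1)
        frac = np.mean(degrees >= min_neighbors)
        if frac > fraction:
            return float(t)
    warnings.warn(
        "no candidate threshold gives "
        f">{fraction:.0%} of cells >= {min_neighbors} neighbors; "
        "returning the largest candidate",
        stacklevel=2,
    )
    return float(candidates[-1])


def build_gene_graph(
    lr_db: LigandReceptorDatabase,
    expr: ExpressionMatrix,
    min_cells_expressing: int = 1,
) -> GeneGraph:
    """Expand LR records to directed gene-level edges, gated on expression.

    Each record's complex is expanded to all (ligand subunit -> receptor
    subunit) ordered gene pairs; an edge is added only when both genes are
    present in ``expr`` and each is nonzero in at least
    ``min_cells_expressing`` cells.  Records naming absent genes are skipped
    (never fatal) and counted in the report.
    """
    gi = {g: k for k, g in enumerate(expr.gene_ids)}
    n_expressing = (expr.values != 0).sum(axis=1)
    m = expr.n_genes
    A = np.zeros((m, m), dtype=np.int8)
    pair_index: dict[tuple[int, int], list[int]] = {}
    n_pairs_absent = n_pairs_gated = n_pairs_added = 0
    records_with_edge: set[int] = set()
    records_touched_absent: set[int] = set()
    for r, rec in enumerate(lr_db):
        for lig in rec.ligand_subunits:
            for recp in rec.receptor_subunits:
                if lig not in gi or recp not in gi:
                    n_pairs_absent += 1
                    records_touched_absent.add(r)
                    continue
                i, j = gi[lig], gi[recp]
                if i == j:
                    continue
                if (
                    n_expressing[i] < min_cells_expressing
                    or n_expressing[j] < min_cells_expressing
                ):
                    n_pairs_gated += 1
                    continue
                if not A[i, j]:
                    n_pairs_added += 1
                A[i, j] = 1
                pair_index.setdefault((i, j), []).append(r)
                records_with_edge.add(r)
    report = {
        "n_records": len(lr_db),
        "n_records_skipped": len(lr_db) - len(records_with_edge),
        "n_records_with_absent_genes": len(records_touched_absent),
        "n_pairs_added": n_pairs_added,
        "n_pairs_absent": n_pairs_absent,
        "n_pairs_failed_gate": n_pairs_gated,
    }
    return GeneGraph(A, list(expr.gene_ids), pair_index, report)


def count_edges_by_distance(
    edges, coords: SpatialCoordinates, bin_edges
) -> np.ndarray:
    """Histogram of directed cell-pair edges by Euclidean length.

    Bins are half-open ``[b_k, b_{k+1})``; edges at or beyond the last bin
    edge are dropped, so the counts sum to the number of in-range edges.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.ndim != 1 or bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be ascending with at least two values")
    edges = list(edges)
    if not edges:
        return np.zeros(bin_edges.size - 1, dtype=int)
    idx = np.asarray(edges, dtype=int)
    lengths = np.linalg.norm(coords.xy[idx[:, 0]] - coords.xy[idx[:, 1]], axis=1)
    lengths = lengths[lengths < bin_edges[-1]]  # enforce half-open last bin
    counts, _ = np.histogram(lengths, bins=bin_edges)
    return counts.astype(int)
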