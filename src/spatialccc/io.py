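"""Readers and writers for the package's on-disk formats.

All tabular I/O is tab-separated with a header row by default.  Sparse
expression can be read from Matrix Market files with two plain-text ID
sidecars.  Internally expression is always genes x cells; the on-disk
orientation is declared by the caller, never guessed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "ExpressionMatrix",
    "SpatialCoordinates",
    "CellTypeLabels",
    "LRRecord",
    "LigandReceptorDatabase",
    "read_expression",
    "write_expression",
    "read_coordinates",
    "write_coordinates",
    "read_labels",
    "write_labels",
    "read_lr_database",
    "write_lr_database",
    "read_edge_list",
    "write_edge_list",
    "read_config",
]


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} IDs")


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x cells expression matrix with ID axes."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression must be a 2-D matrix")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("expression must have at least one gene and one cell")
        if len(self.gene_ids) != m:
            raise ValueError("gene ID count does not match matrix rows")
        if len(self.cell_ids) != n:
            raise ValueError("cell ID count does not match matrix columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")
        if np.any(self.values < 0):
            raise ValueError("negative expression")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None


@dataclass
class SpatialCoordinates:
    """2-D coordinates per cell/spot, in the caller's distance units."""

    xy: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("coordinates must be an n x 2 matrix")
        if len(self.cell_ids) != self.xy.shape[0]:
            raise ValueError("coordinate count does not match cell ID count")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("non-finite coordinates")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_cells(self) -> int:
        return self.xy.shape[0]

    def reorder(self, cell_ids: list[str]) -> "SpatialCoordinates":
        """Return coordinates permuted into the requested cell-ID order."""
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cell_ids if c not in pos]
        if missing:
            raise ValueError(f"coordinate missing for cell {missing[0]!r}")
        idx = [pos[c] for c in cell_ids]
        return SpatialCoordinates(self.xy[idx], list(cell_ids))


@dataclass
class CellTypeLabels:
    """One categorical type label per cell/spot."""

    labels: list[str]
    cell_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) == 0:
            raise ValueError("empty label vector")
        if self.cell_ids is not None:
            self.cell_ids = [str(c) for c in self.cell_ids]
            if len(self.cell_ids) != len(self.labels):
                raise ValueError("label count does not match cell ID count")
            _check_unique(self.cell_ids, "cell")

    @property
    def type_names(self) -> list[str]:
        return sorted(set(self.labels))

    @property
    def n_types(self) -> int:
        return len(set(self.labels))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)


@dataclass
class LRRecord:
    """One ligand-receptor interaction, possibly multi-subunit on either side."""

    ligand_subunits: list[str]
    receptor_subunits: list[str]
    annotation: str = ""

    def __post_init__(self) -> None:
        self.ligand_subunits = [s.strip() for s in self.ligand_subunits]
        self.receptor_subunits = [s.strip() for s in self.receptor_subunits]
        if not self.ligand_subunits or any(not s for s in self.ligand_subunits):
            raise ValueError("ligand field empty")
        if not self.receptor_subunits or any(not s for s in self.receptor_subunits):
            raise ValueError("receptor field empty")


@dataclass
class LigandReceptorDatabase:
    """Ordered collection of ligand-receptor interaction records."""

    records: list[LRRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


# ---------------------------------------------------------------------------
# expression

def read_expression(
    path: str,
    layout: str = "genes-in-rows",
    format: str = "delimited",
    sep: str = "\t",
    gene_ids_path: str | None = None,
    cell_ids_path: str | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix into canonical genes x cells orientation.

    ``layout`` declares the on-disk orientation ("genes-in-rows" or
    "cells-in-rows").  ``format`` is "delimited" (first column = row IDs,
    header = column IDs) or "matrix-market" (requires gene-ID and cell-ID
    sidecar files, one ID per line).
    """
    if layout not in ("genes-in-rows", "cells-in-rows"):
        raise ValueError(f"unknown layout {layout!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "delimited":
        df = pd.read_csv(path, sep=sep, index_col=0)
        values = df.to_numpy(dtype=float)
        row_ids = [str(x) for x in df.index]
        col_ids = [str(x) for x in df.columns]
    elif format == "matrix-market":
        if gene_ids_path is None or cell_ids_path is None:
            base = path[:-4] if path.endswith(".mtx") else path
            gene_ids_path = gene_ids_path or base + ".genes.txt"
            cell_ids_path = cell_ids_path or base + ".cells.txt"
        for p in (gene_ids_path, cell_ids_path):
            if not os.path.exists(p):
                raise FileNotFoundError(f"ID sidecar file missing: {p}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        with open(gene_ids_path) as fh:
            gene_ids = [line.strip() for line in fh if line.strip()]
        with open(cell_ids_path) as fh:
            cell_ids = [line.strip() for line in fh if line.strip()]
        if layout == "genes-in-rows":
            row_ids, col_ids = gene_ids, cell_ids
        else:
            row_ids, col_ids = cell_ids, gene_ids
    else:
        raise ValueError(f"unknown format {format!r}")
    if values.shape != (len(row_ids), len(col_ids)):
        raise ValueError(
            f"dimension mismatch: matrix is {values.shape}, IDs are "
            f"({len(row_ids)}, {len(col_ids)})"
        )
    if layout == "cells-in-rows":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values, row_ids, col_ids)


def write_expression(
    expr: ExpressionMatrix,
    path: str,
    layout: str = "genes-in-rows",
    sep: str = "\t",
) -> None:
    if layout == "genes-in-rows":
        df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.cell_ids)
    elif layout == "cells-in-rows":
        df = pd.DataFrame(expr.values.T, index=expr.cell_ids, columns=expr.gene_ids)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# coordinates and labels

def read_coordinates(path: str, sep: str = "\t") -> SpatialCoordinates:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise ValueError("coordinate file needs cell ID, x, y columns")
    cell_ids = [str(x) for x in df.iloc[:, 0]]
    try:
        xy = df.iloc[:, 1:3].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric coordinates: {exc}") from None
    return SpatialCoordinates(xy, cell_ids)


def write_coordinates(coords: SpatialCoordinates, path: str, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {"cell_id": coords.cell_ids, "x": coords.xy[:, 0], "y": coords.xy[:, 1]}
    )
    df.to_csv(path, sep=sep, index=False)


def read_labels(path: str, sep: str = "\t") -> CellTypeLabels:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError("label file needs cell ID and label columns")
    return CellTypeLabels(
        labels=[str(x) for x in df.iloc[:, 1]],
        cell_ids=[str(x) for x in df.iloc[:, 0]],
    )


def write_labels(labels: CellTypeLabels, path: str, sep: str = "\t") -> None:
    cell_ids = labels.cell_ids
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(len(labels.labels))]
    pd.DataFrame({"cell_id": cell_ids, "cell_type": labels.labels}).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# ligand-receptor tables

def read_lr_database(
    path: str,
    subunit_delimiter: str = "_",
    sep: str = "\t",
    ligand_col: str = "ligand",
    receptor_col: str = "receptor",
    annotation_col: str = "annotation",
) -> LigandReceptorDatabase:
    """Read a CellChatDB-style ligand/receptor table.

    Multi-subunit complexes are encoded as delimiter-joined gene symbols in
    a single cell (e.g. ``R1_R2``); they are kept as subunit lists here and
    expanded to gene-level edges only during gene-graph construction.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    for col in (ligand_col, receptor_col):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in LR table")
    records = []
    for i, row in df.iterrows():
        lig = row[ligand_col]
        rec = row[receptor_col]
        if pd.isna(lig) or pd.isna(rec) or not str(lig).strip() or not str(rec).strip():
            raise ValueError(f"empty ligand or receptor field at row {i}")
        ann = ""
        if annotation_col in df.columns and not pd.isna(row[annotation_col]):
            ann = str(row[annotation_col])
        records.append(
            LRRecord(
                ligand_subunits=str(lig).split(subunit_delimiter),
                receptor_subunits=str(rec).split(subunit_delimiter),
                annotation=ann,
            )
        )
    return LigandReceptorDatabase(records)


def write_lr_database(
    db: LigandReceptorDatabase,
    path: str,
    subunit_delimiter: str = "_",
    sep: str = "\t",
) -> None:
    rows = [
        {
            "ligand": subunit_delimiter.join(r.ligand_subunits),
            "receptor": subunit_delimiter.join(r.receptor_subunits),
            "annotation": r.annotation,
        }
        for r in db.records
    ]
    pd.DataFrame(rows, columns=["ligand", "receptor", "annotation"]).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# edge lists and config

def write_edge_list(edges, path: str, sep: str = "\t") -> None:
    """Write weighted directed edges as a (source, target, weight) TSV.

    ``edges`` is an iterable of (source, target, weight) triples; an empty
    iterable yields a header-only file.
    """
    rows = [
        {"source": str(s), "target": str(t), "weight": float(w)}
        for s, t, w in edges
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep=sep, index=False
    )


def read_edge_list(path: str, sep: str = "\t") -> set[tuple[str, str, float]]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep)
    return {
        (str(r["source"]), str(r["target"]), float(r["weight"]))
        for _, r in df.iterrows()
    }


def read_config(path: str) -> dict:
    """Read a YAML key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
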