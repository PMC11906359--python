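"""Core in-memory containers: expression datasets and design matrices.

The package-internal orientation is genes x cells (matching the linear-model
convention of differential-expression tools); the IO layer transposes
cell x gene inputs such as AnnData at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CellDataset", "DesignMatrix"]


@dataclass
class CellDataset:
    """A genes x cells expression dataset with per-cell metadata.

    Either raw ``counts`` or variance-stabilized ``values`` (or both) must be
    present; ``values`` are computed lazily from counts by the shifted-log
    transform when absent.
    """

    counts: np.ndarray | None = None
    values: np.ndarray | None = None
    gene_ids: np.ndarray | None = None
    cell_ids: np.ndarray | None = None
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts is None and self.values is None:
            raise ValueError("need at least one of counts or values")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if np.any(self.counts < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if not np.all(np.isfinite(self.values)):
                raise ValueError("values must be finite")
        shape = self.counts.shape if self.counts is not None else self.values.shape
        if self.counts is not None and self.values is not None:
            if self.counts.shape != self.values.shape:
                raise ValueError("counts and values shapes differ")
        g, c = shape
        if self.gene_ids is None:
            self.gene_ids = np.array([f"gene_{i}" for i in range(g)])
        else:
            self.gene_ids = np.asarray(self.gene_ids).astype(str)
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell_{i}" for i in range(c)])
        else:
            self.cell_ids = np.asarray(self.cell_ids).astype(str)
        if len(self.gene_ids) != g or len(np.unique(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique and match the number of rows")
        if len(self.cell_ids) != c or len(np.unique(self.cell_ids)) != c:
            raise ValueError("cell_ids must be unique and match the number of columns")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        elif len(self.cell_meta) != c:
            raise ValueError(
                f"cell_meta has {len(self.cell_meta)} rows, expected {c}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def get_values(self, pseudo_count: float = 1.0) -> np.ndarray:
        """Variance-stabilized values, computing the shifted log if needed."""
        if self.values is not None:
            return self.values
        from .preprocessing import shifted_log_transform

        return shifted_log_transform(self.counts, pseudo_count=pseudo_count)


@dataclass
class DesignMatrix:
    """A C x K numeric design matrix with named columns.

    Each row encodes one cell's covariates; a *condition* is a unique row.
    """

    matrix: np.ndarray
    column_names: list[str] = field(default_factory=list)
    formula: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if not self.column_names:
            self.column_names = [f"x{k}" for k in range(self.matrix.shape[1])]
        if len(self.column_names) != self.matrix.shape[1]:
            raise ValueError("column_names length must equal number of columns")
        k = self.matrix.shape[1]
        if np.linalg.matrix_rank(self.matrix) < k:
            raise ValueError(
                f"design matrix is rank deficient (K={k} columns, "
                f"rank {np.linalg.matrix_rank(self.matrix)}); "
                f"check for collinear covariates among {self.column_names}"
            )

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def as_design_array(design, n_cells: int) -> np.ndarray:
    """Coerce a design specification to a validated C x K float array."""
    if design is None:
        return np.ones((n_cells, 1))
    if isinstance(design, DesignMatrix):
        x = design.matrix
    else:
        x = np.atleast_2d(np.asarray(design, dtype=float))
        if x.shape[0] == 1 and n_cells == 1:
            pass
        elif x.shape[0] != n_cells and x.shape[1] == n_cells:
            x = x.T
    if x.shape[0] != n_cells:
        raise ValueError(
            f"design has {x.shape[0]} rows but the data has {n_cells} cells"
        )
    return np.asarray(x, dtype=float)
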