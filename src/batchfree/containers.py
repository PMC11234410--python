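"""In-memory containers for multi-batch expression data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

Matrix = "np.ndarray | sp.spmatrix"


def _n_obs(values) -> int:
    return values.shape[0]


def _to_dense(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.todense())
    return np.asarray(values)


@dataclass
class RawMatrix:
    """A single batch: cell-by-gene expression with identifiers.

    values may be a dense ndarray or any scipy sparse matrix; sparse input is
    kept sparse by every operation that permits it.  Values are non-negative
    (raw counts or log-normalized expression).
    """

    values: object
    cell_ids: list[str]
    gene_ids: list[str]
    batch_id: str = "batch"

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if n != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if p != len(self.gene_ids):
            raise ValueError(
                f"matrix has {p} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if sp.issparse(self.values):
            if self.values.count_nonzero() and self.values.min() < 0:
                raise ValueError("expression values must be non-negative")
        elif np.asarray(self.values).size and np.min(self.values) < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return _to_dense(self.values).astype(float)


@dataclass
class BatchCollection:
    """M >= 2 batches over an identical ordered gene axis.

    ``scale`` records whether values are raw counts or log-normalized
    (``lognorm``); the correction machinery requires lognorm.  ``cell_types``
    is optional and used only for evaluation, never for correction.
    """

    matrices: list
    batch_names: list[str]
    gene_ids: list[str]
    cell_types: list | None = None
    scale: str = "lognorm"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.matrices) < 2:
            raise ValueError("a BatchCollection needs at least two batches")
        if len(self.batch_names) != len(self.matrices):
            raise ValueError("one batch name per matrix required")
        p = len(self.gene_ids)
        for name, m in zip(self.batch_names, self.matrices):
            if m.shape[1] != p:
                raise ValueError(
                    f"batch {name!r} has {m.shape[1]} genes, expected {p}"
                )
        if self.scale not in ("counts", "lognorm"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.cell_types is not None and len(self.cell_types) != self.n_cells:
            raise ValueError("cell_types length must equal total cell count")

    @property
    def n_batches(self) -> int:
        return len(self.matrices)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return sum(m.shape[0] for m in self.matrices)

    @property
    def batch_sizes(self) -> list[int]:
        return [m.shape[0] for m in self.matrices]

    def batch_labels(self) -> np.ndarray:
        """Per-cell batch name, concatenated in batch order."""
        return np.concatenate(
            [np.repeat(name, m.shape[0]) for name, m in zip(self.batch_names, self.matrices)]
        )

    def dense(self, i: int) -> np.ndarray:
        return _to_dense(self.matrices[i]).astype(float)

    def stacked(self) -> np.ndarray:
        """All cells as one dense cell-by-gene matrix, batches concatenated."""
        return np.vstack([self.dense(i) for i in range(self.n_batches)])
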