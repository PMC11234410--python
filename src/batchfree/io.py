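"""Reading and writing expression matrices and metadata.

Supported layouts:

* Matrix Market ``.mtx`` with sidecar ``genes.tsv`` and ``barcodes.tsv``
  files next to the matrix (one ID per line).  The matrix is taken as
  cell-by-gene; a transposed (gene-by-cell) matrix is auto-detected from the
  sidecar lengths and flipped.
* Dense CSV/TSV with cells as rows: header row of gene names, first column
  cell IDs.
* Metadata TSV with columns ``cell_id``, ``batch`` and optional
  ``cell_type``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .containers import RawMatrix


class ParseError(ValueError):
    pass


def _read_ids(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_matrix(path: str, fmt: str | None = None, batch_id: str | None = None) -> RawMatrix:
    """Read one batch from disk.

    ``fmt`` is one of ``mtx``, ``csv``, ``tsv``; inferred from the file
    extension when omitted.  For ``mtx``, sidecars ``genes.tsv`` and
    ``barcodes.tsv`` must sit alongside the matrix file.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    if fmt not in ("mtx", "csv", "tsv"):
        raise ValueError(f"unsupported format {fmt!r}")
    name = batch_id if batch_id is not None else os.path.splitext(os.path.basename(path))[0]

    if fmt == "mtx":
        folder = os.path.dirname(path) or "."
        genes_path = os.path.join(folder, "genes.tsv")
        cells_path = os.path.join(folder, "barcodes.tsv")
        for side in (genes_path, cells_path):
            if not os.path.exists(side):
                raise FileNotFoundError(f"missing sidecar file {side}")
        try:
            mat = mmread(path).tocsr()
        except Exception as exc:  # pragma: no cover - message passthrough
            raise ParseError(f"malformed Matrix Market file {path}: {exc}") from exc
        gene_ids = _read_ids(genes_path)
        cell_ids = _read_ids(cells_path)
        n, p = mat.shape
        if (n, p) == (len(cell_ids), len(gene_ids)):
            pass
        elif (p, n) == (len(cell_ids), len(gene_ids)):
            mat = mat.T.tocsr()  # gene-by-cell on disk
        else:
            raise ValueError(
                f"matrix shape {mat.shape} matches neither {len(cell_ids)} cells x "
                f"{len(gene_ids)} genes nor its transpose"
            )
        return RawMatrix(mat, cell_ids, gene_ids, name)

    sep = "," if fmt == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise ParseError(f"malformed {fmt} file {path}: {exc}") from exc
    return RawMatrix(
        df.to_numpy(dtype=float),
        [str(c) for c in df.index],
        [str(g) for g in df.columns],
        name,
    )


def write_matrix(m: RawMatrix, path: str, fmt: str | None = None) -> None:
    """Write a batch in a layout ``read_matrix`` round-trips."""
    if fmt is None:
        fmt = os.path.splitext(path)[1].lstrip(".").lower()
    if fmt == "mtx":
        folder = os.path.dirname(path) or "."
        os.makedirs(folder, exist_ok=True)
        values = m.values if sp.issparse(m.values) else sp.csr_matrix(np.asarray(m.values))
        mmwrite(path, values, comment="cell-by-gene")
        with open(os.path.join(folder, "genes.tsv"), "w") as fh:
            fh.write("\n".join(m.gene_ids) + "\n")
        with open(os.path.join(folder, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(m.cell_ids) + "\n")
    elif fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(m.dense(), index=m.cell_ids, columns=m.gene_ids)
        df.to_csv(path, sep=sep)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def read_metadata(path: str) -> pd.DataFrame:
    """Read a cell metadata TSV (cell_id, batch, optional cell_type)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_id", "batch"):
        if col not in df.columns:
            raise ParseError(f"metadata file {path} lacks required column {col!r}")
    return df


def write_metadata(path: str, cell_ids, batches, cell_types=None) -> None:
    data = {"cell_id": list(cell_ids), "batch": list(batches)}
    if cell_types is not None:
        data["cell_type"] = list(cell_types)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
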