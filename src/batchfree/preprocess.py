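"""Preprocessing: QC filters, library-size normalization, HVG selection.

The pipeline mirrors common scRNA-seq practice: remove genes expressed
(value > 0) in too few cells, remove cells expressing too few genes,
normalize each cell's library size to a common target, log1p-transform, and
restrict to the top highly variable genes ranked by binned normalized
dispersion.  Filters run genes-first, then cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import BatchCollection, RawMatrix


class EmptyResultError(ValueError):
    """Raised when a filter removes every gene or every cell."""


def _expressed_per_gene(values) -> np.ndarray:
    """Number of cells with value > 0, per gene."""
    if sp.issparse(values):
        return np.asarray((values > 0).sum(axis=0)).ravel()
    return (np.asarray(values) > 0).sum(axis=0)


def _expressed_per_cell(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray((values > 0).sum(axis=1)).ravel()
    return (np.asarray(values) > 0).sum(axis=1)


def filter_genes_min_cells(m: RawMatrix, min_cells_expressed: int = 4) -> RawMatrix:
    """Keep genes expressed (value > 0) in at least ``min_cells_expressed`` cells.

    The default of 4 removes genes seen in at most 3 cells.
    """
    if min_cells_expressed < 1:
        raise ValueError("min_cells_expressed must be >= 1")
    keep = _expressed_per_gene(m.values) >= min_cells_expressed
    if not keep.any():
        raise EmptyResultError("gene filter removed every gene; input looks degenerate")
    values = m.values[:, np.flatnonzero(keep)] if sp.issparse(m.values) else np.asarray(m.values)[:, keep]
    return RawMatrix(values, m.cell_ids, [g for g, k in zip(m.gene_ids, keep) if k], m.batch_id)


def filter_cells_min_genes(m: RawMatrix, min_genes: int = 300) -> RawMatrix:
    """Keep cells expressing at least ``min_genes`` genes (value > 0)."""
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    keep = _expressed_per_cell(m.values) >= min_genes
    if not keep.any():
        raise EmptyResultError("cell filter removed every cell; lower min_genes?")
    values = m.values[np.flatnonzero(keep), :] if sp.issparse(m.values) else np.asarray(m.values)[keep, :]
    return RawMatrix(values, [c for c, k in zip(m.cell_ids, keep) if k], m.gene_ids, m.batch_id)


def normalize_and_log(m: RawMatrix, target_sum: float | str = "median") -> RawMatrix:
    """Scale each cell to a common library size, then log1p.

    ``target_sum='median'`` uses the median of pre-scaling cell totals.
    Zero entries are preserved exactly.
    """
    if sp.issparse(m.values):
        totals = np.asarray(m.values.sum(axis=1)).ravel()
    else:
        totals = np.asarray(m.values, dtype=float).sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError(
            "some cells have zero total counts; run filter_cells_min_genes first"
        )
    target = float(np.median(totals)) if target_sum == "median" else float(target_sum)
    if target <= 0:
        raise ValueError("target_sum must be positive")
    scale = target / totals
    if sp.issparse(m.values):
        out = sp.diags(scale) @ m.values.tocsr()
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(np.asarray(m.values, dtype=float) * scale[:, None])
    return RawMatrix(out, m.cell_ids, m.gene_ids, m.batch_id)


def _dispersion_stats(values) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and dispersion (var/mean) on the expm1 scale."""
    dense = np.asarray(values.todense()) if sp.issparse(values) else np.asarray(values, dtype=float)
    x = np.expm1(dense)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    return mean, disp


def _normalized_dispersion(mean: np.ndarray, disp: np.ndarray, n_bins: int = 20) -> np.ndarray:
    df = pd.DataFrame({"mean": mean, "disp": disp})
    # equal-frequency mean bins; keep >= ~10 genes per bin so the within-bin
    # location/scale estimates are meaningful on small gene panels
    q = max(1, min(n_bins, len(df) // 10))
    try:
        bins = pd.qcut(df["mean"], q=q, duplicates="drop")
    except ValueError:
        bins = pd.Series(0, index=df.index)
    grouped = df.groupby(bins, observed=True)["disp"]
    bin_mean = grouped.transform("mean")
    bin_std = grouped.transform("std").fillna(0.0)
    norm = (df["disp"] - bin_mean) / bin_std.replace(0.0, np.inf)
    return norm.fillna(0.0).to_numpy()


def select_hvg(
    batches: list[RawMatrix],
    n_top: int = 2000,
    n_bins: int = 20,
    per_batch: bool = False,
) -> list[str]:
    """Rank genes by binned normalized dispersion; return the top ``n_top`` IDs.

    Operates on the intersection of gene sets across batches.  By default the
    log-normalized batches are concatenated before computing dispersions;
    with ``per_batch=True`` normalized dispersions are computed within each
    batch and averaged.  Ties break by lexical gene ID so the output is
    deterministic and invariant to cell/batch order.
    """
    common = set(batches[0].gene_ids)
    for b in batches[1:]:
        common &= set(b.gene_ids)
    genes = sorted(common)
    if n_top > len(genes):
        raise ValueError(f"n_top={n_top} exceeds the {len(genes)} common genes")

    aligned = []
    for b in batches:
        idx = [b.gene_ids.index(g) for g in genes]
        dense = b.dense()[:, idx]
        aligned.append(dense)

    if per_batch:
        norms = []
        for dense in aligned:
            mean, disp = _dispersion_stats(dense)
            norms.append(_normalized_dispersion(mean, disp, n_bins))
        score = np.mean(norms, axis=0)
    else:
        mean, disp = _dispersion_stats(np.vstack(aligned))
        score = _normalized_dispersion(mean, disp, n_bins)

    order = sorted(range(len(genes)), key=lambda i: (-score[i], genes[i]))
    return [genes[i] for i in order[:n_top]]


def assemble_collection(
    batches: list[RawMatrix],
    genes: list[str],
    cell_types=None,
    strict: bool = True,
    scale: str = "lognorm",
) -> BatchCollection:
    """Column-align every batch to ``genes`` and build a BatchCollection.

    In strict mode (default) a batch missing any requested gene raises,
    naming the missing IDs; otherwise missing genes are zero-filled.
    """
    if len(batches) < 2:
        raise ValueError("at least two batches are required for integration")
    matrices = []
    for b in batches:
        pos = {g: i for i, g in enumerate(b.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing and strict:
            raise ValueError(
                f"batch {b.batch_id!r} is missing genes: {', '.join(missing[:10])}"
                + ("..." if len(missing) > 10 else "")
            )
        dense = b.dense()
        out = np.zeros((b.n_cells, len(genes)))
        for j, g in enumerate(genes):
            if g in pos:
                out[:, j] = dense[:, pos[g]]
        matrices.append(out)
    return BatchCollection(
        matrices=matrices,
        batch_names=[b.batch_id for b in batches],
        gene_ids=list(genes),
        cell_types=None if cell_types is None else list(cell_types),
        scale=scale,
    )


def preprocess_batches(
    batches: list[RawMatrix],
    min_cells_expressed: int = 4,
    min_genes: int = 300,
    target_sum: float | str = "median",
    n_top: int = 2000,
    cell_types: dict | None = None,
) -> BatchCollection:
    """Full pipeline: filter genes, filter cells, normalize+log, HVG, assemble.

    ``cell_types`` optionally maps cell_id -> label; labels are carried for
    cells surviving the filters, in batch order.
    """
    processed = []
    for b in batches:
        b = filter_genes_min_cells(b, min_cells_expressed)
        b = filter_cells_min_genes(b, min_genes)
        b = normalize_and_log(b, target_sum)
        processed.append(b)
    n_common = len(set.intersection(*(set(b.gene_ids) for b in processed)))
    genes = select_hvg(processed, n_top=min(n_top, n_common))
    labels = None
    if cell_types is not None:
        labels = [cell_types[c] for b in processed for c in b.cell_ids]
    return assemble_collection(processed, genes, cell_types=labels)
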