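"""Positive merge divergence: a two-stage integration metric.

Stage 1 flags *positive* cells: cells whose k-nearest neighbours are
dominated by their own cell type (strict majority by default).  A low
positive rate signals overcorrection — biologically distinct cells mixed
together.  Stage 2 measures, for positive cells only, the *merge
divergence*: the Jensen-Shannon divergence (base-2 logarithm, so bounded in
[0, 1]) between the batch-proportion vector of the cell's neighbourhood and
the global batch proportions of its cell type.  Zero means the cell's
neighbourhood mixes batches exactly as the whole cell type does — batch
effect removed; high values signal residual (under-corrected) batch
structure.  Comparing against the *cell type's* global proportions (not the
whole dataset's) is what keeps the metric from penalizing batch-specific
cell types that legitimately occupy one batch.

Summary scores: positive rate = #positive / #cells, and the median merge
divergence over positive cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial.distance import jensenshannon


@dataclass
class PMDResult:
    positive_flags: np.ndarray
    merge_divergence: np.ndarray  # per positive cell, in positive-cell order
    positive_rate: float
    median_divergence: float
    k_nn: int
    majority_threshold: float

    def to_dict(self) -> dict:
        return {
            "positive_rate": self.positive_rate,
            "median_divergence": self.median_divergence,
            "k_nn": self.k_nn,
            "threshold": self.majority_threshold,
        }


def build_knn(embedding: np.ndarray, k_nn: int, metric: str = "euclidean",
              block: int = 2048) -> np.ndarray:
    """Exact k-nearest neighbours (self excluded), ties broken by lower index.

    Distances are computed blockwise against all points and sorted with a
    stable sort, so equidistant neighbours resolve deterministically.
    """
    if metric != "euclidean":
        raise ValueError("only the euclidean metric is supported")
    emb = np.atleast_2d(np.asarray(embedding, dtype=float))
    n = emb.shape[0]
    if k_nn >= n:
        raise ValueError(f"k_nn={k_nn} must be smaller than the {n} cells")
    sq = np.sum(emb ** 2, axis=1)
    neighbors = np.empty((n, k_nn), dtype=int)
    for start in range(0, n, block):
        stop = min(start + block, n)
        d2 = sq[start:stop, None] - 2.0 * emb[start:stop] @ emb.T + sq[None, :]
        np.maximum(d2, 0.0, out=d2)
        for r in range(start, stop):
            d2[r - start, r] = np.inf  # exclude self
        order = np.argsort(d2, axis=1, kind="stable")
        neighbors[start:stop] = order[:, :k_nn]
    return neighbors


def classify_positive(p: int, neighbors: np.ndarray, cell_types: np.ndarray,
                      majority_threshold: float = 0.5) -> bool:
    """Positive iff the same-type fraction among p's neighbours strictly
    exceeds the threshold."""
    cell_types = np.asarray(cell_types)
    if cell_types[p] is None:
        raise ValueError(f"cell {p} has no cell-type label")
    same = np.mean(cell_types[neighbors[p]] == cell_types[p])
    return bool(same > majority_threshold)


def js_divergence(f: np.ndarray, g: np.ndarray, base: float = 2.0) -> float:
    """Jensen-Shannon divergence between two proportion vectors.

    With base-2 logarithms the value lies in [0, 1]; 0*log0 terms are zero.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    if f.shape != g.shape:
        raise ValueError(f"profile length mismatch: {f.shape} vs {g.shape}")
    return float(jensenshannon(f, g, base=base) ** 2)


def _batch_profiles(batch_labels: np.ndarray, batch_order: np.ndarray) -> dict:
    return {b: i for i, b in enumerate(batch_order)}


def merge_divergence(p: int, neighbors: np.ndarray, batch_labels: np.ndarray,
                     cell_types: np.ndarray, batch_order=None) -> float:
    """JS divergence between cell p's neighbourhood batch proportions and its
    cell type's global batch proportions."""
    batch_labels = np.asarray(batch_labels)
    cell_types = np.asarray(cell_types)
    if batch_order is None:
        batch_order = np.unique(batch_labels)
    index = _batch_profiles(batch_labels, batch_order)
    M = len(batch_order)
    f_hat = np.zeros(M)
    for b in batch_labels[neighbors[p]]:
        f_hat[index[b]] += 1
    f_hat /= f_hat.sum()
    mask = cell_types == cell_types[p]
    f_c = np.zeros(M)
    for b in batch_labels[mask]:
        f_c[index[b]] += 1
    f_c /= f_c.sum()
    return js_divergence(f_hat, f_c)


def pmd(embedding: np.ndarray, cell_types, batch_labels, k_nn: int = 30,
        majority_threshold: float = 0.5) -> PMDResult:
    """Two-stage metric over an embedding with cell-type and batch labels."""
    embedding = np.atleast_2d(np.asarray(embedding, dtype=float))
    cell_types = np.asarray(cell_types)
    batch_labels = np.asarray(batch_labels)
    n = embedding.shape[0]
    if len(cell_types) != n or len(batch_labels) != n:
        raise ValueError("embedding, cell_types and batch_labels must have equal length")
    batch_order = np.unique(batch_labels)
    if len(batch_order) < 2:
        raise ValueError("the metric requires at least two batches")
    neighbors = build_knn(embedding, k_nn)

    same_frac = np.array([
        np.mean(cell_types[neighbors[p]] == cell_types[p]) for p in range(n)
    ])
    flags = same_frac > majority_threshold

    index = {b: i for i, b in enumerate(batch_order)}
    M = len(batch_order)
    codes = np.array([index[b] for b in batch_labels])
    # global per-type batch proportions
    type_profiles = {}
    for t in np.unique(cell_types):
        counts = np.bincount(codes[cell_types == t], minlength=M).astype(float)
        type_profiles[t] = counts / counts.sum()

    divergences = []
    for p in np.flatnonzero(flags):
        counts = np.bincount(codes[neighbors[p]], minlength=M).astype(float)
        f_hat = counts / counts.sum()
        divergences.append(js_divergence(f_hat, type_profiles[cell_types[p]]))
    divergences = np.asarray(divergences)
    return PMDResult(
        positive_flags=flags,
        merge_divergence=divergences,
        positive_rate=float(np.mean(flags)),
        median_divergence=float(np.median(divergences)) if divergences.size else float("nan"),
        k_nn=k_nn,
        majority_threshold=majority_threshold,
    )


def pca_reduce(x: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Optional linear reduction for feeding high-dimensional data to pmd."""
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ vt[:n_components].T


def permutation_test(x, y, n_perm: int = 9999, sided: str = "two",
                     rng=None, exhaustive: bool = False) -> float:
    """Permutation test on the difference of group means.

    The statistic is mean(x) - mean(y).  With ``exhaustive=True`` all
    distinct group splits are enumerated and the p-value is the exact
    fraction of splits at least as extreme as observed; otherwise ``n_perm``
    random splits are drawn and the add-one-corrected estimate
    (1 + #extreme) / (1 + n_perm) is returned.  ``sided`` is ``two``,
    ``larger`` (mean(x) - mean(y) large) or ``smaller``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if sided not in ("two", "larger", "smaller"):
        raise ValueError(f"unknown alternative {sided!r}")
    pooled = np.concatenate([x, y])
    nx, n = x.size, pooled.size
    observed = float(x.mean() - y.mean())

    def extreme(diff):
        if sided == "two":
            return abs(diff) >= abs(observed) - 1e-12
        if sided == "larger":
            return diff >= observed - 1e-12
        return -diff >= -observed - 1e-12

    if exhaustive:
        hits = total = 0
        for idx in combinations(range(n), nx):
            sel = np.zeros(n, dtype=bool)
            sel[list(idx)] = True
            diff = float(pooled[sel].mean() - pooled[~sel].mean())
            hits += extreme(diff)
            total += 1
        return hits / total

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        diff = float(pooled[perm[:nx]].mean() - pooled[perm[nx:]].mean())
        hits += extreme(diff)
    return (1 + hits) / (1 + n_perm)
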