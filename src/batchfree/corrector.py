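"""The corrector network C(x, b): additive batch-effect correction.

A cell's log-expression vector x passes through a shared three-layer
fully-connected stack (leaky-ReLU, leaky-ReLU, tanh head) producing an
unscaled correction vector y in gene space.  A batch-specific affine layer
(BS-Norm) rescales it per batch, z = a_b * y + b_b, separating what is
unique to each batch from what is common to all.  The corrected expression
is max(x + z, 0): the residual addition keeps the output in the original
gene space and the clamp forbids negative expression.

Because the tanh head bounds y in (-1, 1), the correction magnitude per
gene is bounded by |a_b| + |b_b|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import glorot_uniform, leaky_relu, leaky_relu_grad
from .containers import BatchCollection


@dataclass
class CorrectorParams:
    """Weights of the shared stack plus per-batch BS-Norm scale/bias."""

    params: dict
    input_dim: int
    hidden_dims: tuple
    n_batches: int
    negative_slope: float = 0.2
    seed: int | None = None

    def copy(self) -> "CorrectorParams":
        return CorrectorParams(
            {k: v.copy() for k, v in self.params.items()},
            self.input_dim, self.hidden_dims, self.n_batches,
            self.negative_slope, self.seed,
        )


@dataclass
class CorrectionOutput:
    corrected: np.ndarray
    correction_vector: np.ndarray
    cache: dict = field(default_factory=dict, repr=False)


def init_corrector(
    input_dim: int,
    hidden_dims: tuple = (256, 256),
    n_batches: int = 2,
    seed: int = 0,
    negative_slope: float = 0.2,
    scalar_bs: bool = False,
) -> CorrectorParams:
    """Seeded initialization; BS-Norm starts as the identity (a=1, b=0).

    With ``scalar_bs`` each batch carries a single scale/bias instead of
    per-gene vectors.
    """
    if input_dim < 1 or any(h < 1 for h in hidden_dims):
        raise ValueError("dimensions must be positive")
    if n_batches < 2:
        raise ValueError("n_batches must be >= 2")
    h1, h2 = hidden_dims
    rng = np.random.default_rng(seed)
    bs_dim = 1 if scalar_bs else input_dim
    params = {
        "W1": glorot_uniform(rng, input_dim, h1),
        "b1": np.zeros(h1),
        "W2": glorot_uniform(rng, h1, h2),
        "b2": np.zeros(h2),
        "W3": glorot_uniform(rng, h2, input_dim),
        "b3": np.zeros(input_dim),
        "bs_scale": np.ones((n_batches, bs_dim)),
        "bs_bias": np.zeros((n_batches, bs_dim)),
    }
    return CorrectorParams(params, input_dim, tuple(hidden_dims), n_batches,
                           negative_slope, seed)


def bs_norm(y: np.ndarray, batch_index: int, params: CorrectorParams) -> np.ndarray:
    """Batch-specific affine transform z = a_i * y + b_i (elementwise)."""
    if not 0 <= batch_index < params.n_batches:
        raise IndexError(f"batch_index {batch_index} out of range [0, {params.n_batches})")
    a = params.params["bs_scale"][batch_index]
    b = params.params["bs_bias"][batch_index]
    return a * y + b


def correct_cells(x: np.ndarray, batch_index: int, params: CorrectorParams,
                  keep_cache: bool = False) -> CorrectionOutput:
    """Forward pass: corrected = max(x + BS-Norm(stack(x)), 0).

    ``keep_cache`` retains intermediate activations for backpropagation.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.input_dim:
        raise ValueError(f"input has {x.shape[1]} genes, corrector expects {params.input_dim}")
    if not 0 <= batch_index < params.n_batches:
        raise IndexError(f"batch_index {batch_index} out of range [0, {params.n_batches})")
    P = params.params
    s = params.negative_slope
    pre1 = x @ P["W1"] + P["b1"]
    h1 = leaky_relu(pre1, s)
    pre2 = h1 @ P["W2"] + P["b2"]
    h2 = leaky_relu(pre2, s)
    y = np.tanh(h2 @ P["W3"] + P["b3"])
    z = P["bs_scale"][batch_index] * y + P["bs_bias"][batch_index]
    corrected = np.maximum(x + z, 0.0)
    cache = {}
    if keep_cache:
        cache = {"x": x, "pre1": pre1, "h1": h1, "pre2": pre2, "h2": h2,
                 "y": y, "z": z, "batch_index": batch_index}
    return CorrectionOutput(corrected, z, cache)


def corrector_backward(out: CorrectionOutput, params: CorrectorParams,
                       d_corrected: np.ndarray) -> dict:
    """Gradients of a scalar loss w.r.t. every corrector parameter.

    ``d_corrected`` is dL/d(corrected), row-per-cell.  The ReLU clamp gates
    the gradient: cells clamped to zero receive none.
    """
    c = out.cache
    if not c:
        raise ValueError("forward pass must be run with keep_cache=True")
    P = params.params
    s = params.negative_slope
    bi = c["batch_index"]
    gate = (c["x"] + c["z"]) > 0
    dz = d_corrected * gate

    grads = {k: np.zeros_like(v) for k, v in P.items()}
    y = c["y"]
    a = P["bs_scale"][bi]
    if a.shape[0] == 1:  # scalar BS-Norm
        grads["bs_scale"][bi] = np.sum(dz * y)
        grads["bs_bias"][bi] = np.sum(dz)
    else:
        grads["bs_scale"][bi] = np.sum(dz * y, axis=0)
        grads["bs_bias"][bi] = np.sum(dz, axis=0)
    dy = dz * a
    dpre3 = dy * (1.0 - y * y)
    grads["W3"] = c["h2"].T @ dpre3
    grads["b3"] = dpre3.sum(axis=0)
    dh2 = dpre3 @ P["W3"].T
    dpre2 = dh2 * leaky_relu_grad(c["pre2"], s)
    grads["W2"] = c["h1"].T @ dpre2
    grads["b2"] = dpre2.sum(axis=0)
    dh1 = dpre2 @ P["W2"].T
    dpre1 = dh1 * leaky_relu_grad(c["pre1"], s)
    grads["W1"] = c["x"].T @ dpre1
    grads["b1"] = dpre1.sum(axis=0)
    return grads


def apply_full(collection: BatchCollection, params: CorrectorParams,
               block_size: int = 2048) -> BatchCollection:
    """Correct every batch with its own batch index, streaming in blocks."""
    if collection.n_genes != params.input_dim:
        raise ValueError(
            f"collection has {collection.n_genes} genes, corrector expects {params.input_dim}"
        )
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    corrected = []
    for i in range(collection.n_batches):
        dense = collection.dense(i)
        blocks = [
            correct_cells(dense[start:start + block_size], i, params).corrected
            for start in range(0, dense.shape[0], block_size)
        ]
        corrected.append(np.vstack(blocks))
    return BatchCollection(
        matrices=corrected,
        batch_names=list(collection.batch_names),
        gene_ids=list(collection.gene_ids),
        cell_types=collection.cell_types,
        scale="lognorm",
        meta=dict(collection.meta),
    )
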