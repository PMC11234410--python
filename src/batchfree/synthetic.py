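"""Synthetic multi-batch scRNA-seq-like data with known ground truth.

The generator works directly in log-expression space, where the corrector
operates: each cell type has a mean log-expression program, and each batch
distorts it with a per-gene multiplicative factor (scale) and an additive
offset (shift), plus Gaussian noise and optional dropout.  The composition
matrix (batches x types) sets unequal batch sizes and batch-specific cell
types (zero counts).  A count-scale mode (Poisson sampling of
exponentiated means) exists to exercise the preprocessing pipeline.

This is a deliberately idealized model: real scRNA-seq exhibits
overdispersed counts, gene-gene correlation and expression-dependent
dropout that the generator does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import BatchCollection, RawMatrix


@dataclass
class SyntheticDesign:
    n_batches: int
    n_genes: int
    cell_type_programs: np.ndarray  # (T, p) mean log-expression per type
    composition: np.ndarray         # (M, T) cell counts per batch per type
    batch_shift: np.ndarray         # (M, p) additive log-space offsets
    batch_scale: np.ndarray         # (M, p) multiplicative log-space factors
    type_names: list = field(default_factory=list)
    batch_names: list = field(default_factory=list)
    noise_sd: float = 0.3
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_type_programs = np.asarray(self.cell_type_programs, dtype=float)
        self.composition = np.asarray(self.composition, dtype=int)
        self.batch_shift = np.asarray(self.batch_shift, dtype=float)
        self.batch_scale = np.asarray(self.batch_scale, dtype=float)
        M, T, p = self.n_batches, self.cell_type_programs.shape[0], self.n_genes
        if M < 2:
            raise ValueError("n_batches must be >= 2")
        if p < 2:
            raise ValueError("n_genes must be >= 2")
        if self.cell_type_programs.shape != (T, p):
            raise ValueError("cell_type_programs must be (n_types, n_genes)")
        if self.composition.shape != (M, T):
            raise ValueError(f"composition must be ({M}, {T})")
        if (self.composition < 0).any():
            raise ValueError("composition entries must be >= 0")
        shared = ((self.composition > 0).sum(axis=0) >= 2).any()
        if not shared:
            raise ValueError("at least one cell type must be shared by >= 2 batches")
        if self.batch_shift.shape != (M, p) or self.batch_scale.shape != (M, p):
            raise ValueError("batch_shift/batch_scale must be (n_batches, n_genes)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not self.type_names:
            self.type_names = [f"type{t}" for t in range(T)]
        if not self.batch_names:
            self.batch_names = [f"batch{i}" for i in range(M)]

    @property
    def n_types(self) -> int:
        return self.cell_type_programs.shape[0]


@dataclass
class SyntheticTruth:
    cell_types: np.ndarray
    batch_labels: np.ndarray
    clean: np.ndarray        # per-cell program matrix, before batch effect/noise
    batch_shift: np.ndarray
    batch_scale: np.ndarray
    design: SyntheticDesign


def simulate(design: SyntheticDesign) -> tuple:
    """Draw one dataset: returns (BatchCollection, SyntheticTruth).

    Observed log value for a cell of type t in batch i at gene g:
    max(0, scale[i,g] * program[t,g] + shift[i,g] + N(0, noise_sd)), then
    Bernoulli dropout to zero.  Fully deterministic under the design seed.
    """
    rng = np.random.default_rng(design.seed)
    matrices, types, batches, clean_rows = [], [], [], []
    for i in range(design.n_batches):
        rows = []
        for t in range(design.n_types):
            count = design.composition[i, t]
            if count == 0:
                continue
            program = design.cell_type_programs[t]
            mean = design.batch_scale[i] * program + design.batch_shift[i]
            observed = np.tile(mean, (count, 1))
            if design.noise_sd > 0:
                observed += rng.normal(0.0, design.noise_sd, size=(count, design.n_genes))
            observed = np.maximum(0.0, observed)
            if design.dropout_rate > 0:
                keep = rng.random(observed.shape) >= design.dropout_rate
                observed = observed * keep
            rows.append(observed)
            types.extend([design.type_names[t]] * count)
            clean_rows.append(np.tile(program, (count, 1)))
        matrices.append(np.vstack(rows))
        batches.extend([design.batch_names[i]] * matrices[-1].shape[0])
    collection = BatchCollection(
        matrices=matrices,
        batch_names=list(design.batch_names),
        gene_ids=[f"gene{g}" for g in range(design.n_genes)],
        cell_types=list(types),
        scale="lognorm",
    )
    truth = SyntheticTruth(
        cell_types=np.asarray(types),
        batch_labels=np.asarray(batches),
        clean=np.vstack(clean_rows),
        batch_shift=design.batch_shift,
        batch_scale=design.batch_scale,
        design=design,
    )
    return collection, truth


def simulate_counts(design: SyntheticDesign) -> list:
    """Count-scale variant: Poisson draws around exponentiated log means.

    Returns one RawMatrix of raw counts per batch, suitable as input to the
    preprocessing pipeline.
    """
    rng = np.random.default_rng(design.seed + 1)
    out = []
    for i in range(design.n_batches):
        rows, cells = [], []
        k = 0
        for t in range(design.n_types):
            count = design.composition[i, t]
            if count == 0:
                continue
            mean = np.maximum(
                0.0, design.batch_scale[i] * design.cell_type_programs[t] + design.batch_shift[i]
            )
            lam = np.expm1(mean)
            rows.append(rng.poisson(np.tile(lam, (count, 1))))
            cells.extend([f"{design.batch_names[i]}_c{k + j}" for j in range(count)])
            k += count
        out.append(RawMatrix(
            np.vstack(rows).astype(float), cells,
            [f"gene{g}" for g in range(design.n_genes)], design.batch_names[i],
        ))
    return out


def _programs(rng: np.random.Generator, n_types: int, p: int,
              marker_frac: float = 0.1, similar_pair: tuple | None = None) -> np.ndarray:
    """Random mean log-expression programs with per-type marker blocks."""
    base = rng.uniform(0.5, 1.5, size=p)
    programs = np.tile(base, (n_types, 1))
    n_markers = max(2, int(marker_frac * p))
    for t in range(n_types):
        idx = rng.choice(p, size=n_markers, replace=False)
        programs[t, idx] += rng.uniform(1.5, 3.0, size=n_markers)
    if similar_pair is not None:
        a, b = similar_pair
        programs[b] = programs[a] + rng.normal(0.0, 0.15, size=p)
        idx = rng.choice(p, size=max(2, n_markers // 4), replace=False)
        programs[b, idx] += rng.uniform(0.8, 1.5, size=len(idx))
    return np.clip(programs, 0.0, None)


def preset(name: str, seed: int = 0) -> SyntheticDesign:
    """Documented small designs used throughout the test suite.

    * ``no_effect``      — two batches, identical distributions.
    * ``shift_only``     — three batches, per-batch constant log-space shifts.
    * ``batch_specific_types`` — a shared type plus one exclusive type per batch.
    * ``dc_like``        — two batches, four types, a batch-specific pair of
      biologically similar types plus two shared types (small batch effect).
    * ``cellline_like``  — three batches: type A only, type B only, and mixed.
    """
    rng = np.random.default_rng(seed + 17)
    if name == "no_effect":
        p, T = 100, 3
        programs = _programs(rng, T, p)
        comp = np.array([[250, 250, 250], [250, 250, 250]])
        shift = np.zeros((2, p))
        scale = np.ones((2, p))
        return SyntheticDesign(2, p, programs, comp, shift, scale,
                               noise_sd=0.3, dropout_rate=0.0, seed=seed)
    if name == "shift_only":
        p, T = 300, 3
        programs = _programs(rng, T, p)
        comp = np.array([[200, 150, 150], [150, 200, 150], [150, 150, 200]])
        shift = np.vstack([np.zeros(p), np.full(p, 0.5), np.full(p, -0.35)])
        scale = np.ones((3, p))
        return SyntheticDesign(3, p, programs, comp, shift, scale,
                               noise_sd=0.3, dropout_rate=0.0, seed=seed)
    if name == "batch_specific_types":
        p, T = 200, 3  # type0 shared; type1 only batch0; type2 only batch1
        programs = _programs(rng, T, p, similar_pair=(1, 2))
        comp = np.array([[300, 150, 0], [300, 0, 150]])
        shift = np.vstack([np.zeros(p), rng.uniform(0.2, 0.5, p)])
        scale = np.ones((2, p))
        return SyntheticDesign(2, p, programs, comp, shift, scale,
                               noise_sd=0.3, dropout_rate=0.0, seed=seed)
    if name == "dc_like":
        p, T = 200, 4  # types 0,1 shared; 2 only batch0; 3 only batch1; 2~3 similar
        programs = _programs(rng, T, p, similar_pair=(2, 3))
        comp = np.array([[150, 120, 100, 0], [140, 130, 0, 100]])
        shift = np.vstack([np.zeros(p), rng.uniform(0.1, 0.3, p)])
        scale = np.ones((2, p))
        return SyntheticDesign(2, p, programs, comp, shift, scale,
                               noise_sd=0.3, dropout_rate=0.0, seed=seed)
    if name == "cellline_like":
        p, T = 150, 2
        programs = _programs(rng, T, p)
        comp = np.array([[300, 0], [0, 320], [160, 180]])
        shift = np.vstack([np.zeros(p), np.full(p, 0.4), np.full(p, -0.25)])
        scale = np.vstack([np.ones(p), np.ones(p), np.ones(p)])
        return SyntheticDesign(3, p, programs, comp, shift, scale,
                               noise_sd=0.3, dropout_rate=0.0, seed=seed)
    raise ValueError(f"unknown preset {name!r}")
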