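"""The M-batch adversarial objective.

For M batches with empirical distributions P_1..P_M, critic j estimates

    L_w^j = E_{x~P_j}[W_j(C(x, j))] - (1/(M-1)) sum_{i != j} E_{x~P_i}[W_j(C(x, i))]

the Wasserstein-1 distance between corrected batch j and the corrected
mixture of the other batches.  The total loss sums L_w^j over j, which can
be rewritten as sum_{i,j} f(i,j) E_{x~P_i}[W_j(C(x, i))] with the pair
coefficient f(i,j) = 1 if i = j else -1/(M-1).  Every row of f sums to
zero, so no batch plays a privileged reference role.

A soft Lipschitz constraint adds, for each ordered batch pair (i, j), the
penalty lambda * E_{s~Q_ij}[(||grad_s W_j(s)||_2 - 1)^2], where Q_ij is the
linear interpolation s = (1-t) x + t y between corrected cells of batches i
and j with t ~ U[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corrector import CorrectorParams, correct_cells
from .critic import CriticEnsemble, critic_score, penalty_and_param_grads


@dataclass
class ObjectiveConfig:
    lambda_gp: float = 10.0
    include_diagonal_pairs: bool = True
    interpolation_draws: int = 1

    def __post_init__(self) -> None:
        if self.lambda_gp < 0:
            raise ValueError("lambda_gp must be non-negative")
        if self.interpolation_draws < 1:
            raise ValueError("interpolation_draws must be >= 1")

    def to_dict(self) -> dict:
        return {
            "lambda_gp": self.lambda_gp,
            "include_diagonal_pairs": self.include_diagonal_pairs,
            "interpolation_draws": self.interpolation_draws,
        }


@dataclass
class LossBreakdown:
    per_critic_wasserstein: np.ndarray
    penalty_total: float
    lambda_gp: float

    @property
    def total(self) -> float:
        return float(np.sum(self.per_critic_wasserstein) + self.lambda_gp * self.penalty_total)


def pair_coefficient(i: int, j: int, M: int) -> float:
    """f(i, j) = 1 when i = j, else -1/(M-1)."""
    if M < 2:
        raise ValueError("M must be >= 2")
    if not (0 <= i < M and 0 <= j < M):
        raise ValueError(f"indices ({i}, {j}) out of range for M={M}")
    return 1.0 if i == j else -1.0 / (M - 1)


def interpolate(x_rows: np.ndarray, y_rows: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Per-row linear interpolation (1-t) x + t y with t ~ U[0, 1]."""
    x_rows = np.atleast_2d(np.asarray(x_rows, dtype=float))
    y_rows = np.atleast_2d(np.asarray(y_rows, dtype=float))
    if x_rows.shape != y_rows.shape:
        raise ValueError(f"shape mismatch: {x_rows.shape} vs {y_rows.shape}")
    t = rng.uniform(0.0, 1.0, size=(x_rows.shape[0], 1))
    return (1.0 - t) * x_rows + t * y_rows


def gradient_penalty(ensemble: CriticEnsemble, j: int, s: np.ndarray) -> float:
    """Mean over rows of (||grad_s W_j(s)||_2 - 1)^2, without the lambda factor."""
    value, _ = penalty_and_param_grads(ensemble, j, s)
    return value


def wasserstein_term(ensemble: CriticEnsemble, j: int,
                     corrected_minibatches: list) -> float:
    """L_w^j: mean critic-j score on batch j minus the mean over other batches."""
    M = ensemble.n_batches
    if len(corrected_minibatches) != M:
        raise ValueError(f"expected {M} minibatches, got {len(corrected_minibatches)}")
    means = []
    for i, mb in enumerate(corrected_minibatches):
        mb = np.atleast_2d(np.asarray(mb))
        if mb.shape[0] == 0:
            raise ValueError(f"minibatch {i} is empty")
        means.append(float(np.mean(critic_score(ensemble, j, mb))))
    return float(sum(pair_coefficient(i, j, M) * means[i] for i in range(M)))


def pair_interpolants(corrected: list, i: int, j: int, cfg: ObjectiveConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Interpolated samples between corrected batches i and j.

    Rows are shuffled independently and zipped up to the shorter minibatch.
    """
    xi = np.atleast_2d(corrected[i])
    xj = np.atleast_2d(corrected[j])
    n = min(xi.shape[0], xj.shape[0])
    draws = []
    for _ in range(cfg.interpolation_draws):
        pi = rng.permutation(xi.shape[0])[:n]
        pj = rng.permutation(xj.shape[0])[:n]
        draws.append(interpolate(xi[pi], xj[pj], rng))
    return np.vstack(draws)


def total_objective(ensemble: CriticEnsemble, corrector: CorrectorParams,
                    raw_minibatches: list, cfg: ObjectiveConfig,
                    rng: np.random.Generator) -> LossBreakdown:
    """Full objective value on one set of per-batch minibatches.

    Corrects each minibatch with its own batch index, sums the M per-critic
    Wasserstein estimates, and accumulates the gradient penalty over ordered
    batch pairs (i, j) against critic j (diagonal pairs included by default).
    """
    M = ensemble.n_batches
    if len(raw_minibatches) != M:
        raise ValueError(f"expected {M} minibatches, got {len(raw_minibatches)}")
    corrected = [correct_cells(mb, i, corrector).corrected
                 for i, mb in enumerate(raw_minibatches)]
    per_critic = np.array([wasserstein_term(ensemble, j, corrected) for j in range(M)])
    penalty_total = 0.0
    for i in range(M):
        for j in range(M):
            if i == j and not cfg.include_diagonal_pairs:
                continue
            s = pair_interpolants(corrected, i, j, cfg, rng)
            penalty_total += gradient_penalty(ensemble, j, s)
    return LossBreakdown(per_critic, float(penalty_total), cfg.lambda_gp)
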