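"""The critic ensemble W_1..W_M (one scalar-valued network per batch).

Each critic is a three-layer fully-connected network (leaky-ReLU, leaky-ReLU,
linear head) mapping a cell's expression vector to a real number.  Critic j
estimates, via the Kantorovich-Rubinstein dual, the Wasserstein-1 distance
between the distribution of batch j and the mixture of the other batches.
The 1-Lipschitz constraint is enforced softly by a gradient penalty, never
by weight clipping, so the critics contain no normalization layers (which
would break per-sample input-gradient semantics).

Backpropagation, the input gradient, and the double backprop needed for the
gradient-penalty parameter gradients are written out analytically; the
leaky-ReLU second derivative is zero almost everywhere, so activation
derivative factors are treated as locally constant, matching what reverse-mode
autodiff computes for piecewise-linear activations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import glorot_uniform, leaky_relu, leaky_relu_grad


@dataclass
class CriticEnsemble:
    critics: list  # list of dicts with V1, c1, V2, c2, v3, c3
    input_dim: int
    hidden_dims: tuple
    negative_slope: float = 0.2
    seed: int | None = None

    @property
    def n_batches(self) -> int:
        return len(self.critics)

    def copy(self) -> "CriticEnsemble":
        return CriticEnsemble(
            [{k: v.copy() for k, v in c.items()} for c in self.critics],
            self.input_dim, self.hidden_dims, self.negative_slope, self.seed,
        )


def init_critics(
    input_dim: int,
    hidden_dims: tuple = (256, 64),
    n_batches: int = 2,
    seed: int = 0,
    negative_slope: float = 0.2,
) -> CriticEnsemble:
    """M independently seeded critics (seed offset by batch index).

    The scalar head starts at zero so the critic's input-gradient field is
    zero at initialization: the first data-term updates then set its
    direction before the gradient penalty amplifies its norm toward 1.
    (With a random head the penalty can lock the field onto an arbitrary
    initial direction, a spurious optimum that is hard to escape when the
    support is low-dimensional.)
    """
    if input_dim < 1 or any(h < 1 for h in hidden_dims):
        raise ValueError("dimensions must be positive")
    if n_batches < 2:
        raise ValueError("n_batches must be >= 2")
    h1, h2 = hidden_dims
    critics = []
    for j in range(n_batches):
        rng = np.random.default_rng(seed + j)
        critics.append({
            "V1": glorot_uniform(rng, input_dim, h1),
            "c1": np.zeros(h1),
            "V2": glorot_uniform(rng, h1, h2),
            "c2": np.zeros(h2),
            "v3": np.zeros((h2, 1)),
            "c3": np.zeros(1),
        })
    return CriticEnsemble(critics, input_dim, tuple(hidden_dims), negative_slope, seed)


def _forward(c: dict, x: np.ndarray, slope: float) -> dict:
    pre1 = x @ c["V1"] + c["c1"]
    h1 = leaky_relu(pre1, slope)
    pre2 = h1 @ c["V2"] + c["c2"]
    h2 = leaky_relu(pre2, slope)
    score = (h2 @ c["v3"]).ravel() + c["c3"][0]
    return {"x": x, "pre1": pre1, "h1": h1, "pre2": pre2, "h2": h2, "score": score}


def _check_index(ensemble: CriticEnsemble, j: int) -> None:
    if not 0 <= j < ensemble.n_batches:
        raise IndexError(f"critic index {j} out of range [0, {ensemble.n_batches})")


def critic_score(ensemble: CriticEnsemble, j: int, x: np.ndarray) -> np.ndarray:
    """One scalar per input row from critic j."""
    _check_index(ensemble, j)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != ensemble.input_dim:
        raise ValueError(f"input has {x.shape[1]} features, critic expects {ensemble.input_dim}")
    return _forward(ensemble.critics[j], x, ensemble.negative_slope)["score"]


def critic_input_gradient(ensemble: CriticEnsemble, j: int, s: np.ndarray) -> np.ndarray:
    """Row-wise gradient of critic j's scalar output w.r.t. its own input."""
    _check_index(ensemble, j)
    s = np.atleast_2d(np.asarray(s, dtype=float))
    if s.shape[1] != ensemble.input_dim:
        raise ValueError(f"input has {s.shape[1]} features, critic expects {ensemble.input_dim}")
    c = ensemble.critics[j]
    slope = ensemble.negative_slope
    cache = _forward(c, s, slope)
    d2 = leaky_relu_grad(cache["pre2"], slope)  # (n, h2)
    d1 = leaky_relu_grad(cache["pre1"], slope)  # (n, h1)
    u2 = d2 * c["v3"].ravel()                   # (n, h2)
    u1 = d1 * (u2 @ c["V2"].T)                  # (n, h1)
    return u1 @ c["V1"].T                       # (n, p)


def critic_param_grads(ensemble: CriticEnsemble, j: int, x: np.ndarray,
                       d_score: np.ndarray) -> dict:
    """Gradients of sum_r d_score[r] * W_j(x_r) w.r.t. critic j's parameters."""
    _check_index(ensemble, j)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    c = ensemble.critics[j]
    slope = ensemble.negative_slope
    cache = _forward(c, x, slope)
    d_score = np.asarray(d_score, dtype=float).ravel()[:, None]  # (n, 1)
    grads = {}
    grads["v3"] = cache["h2"].T @ d_score
    grads["c3"] = np.array([d_score.sum()])
    dh2 = d_score @ c["v3"].T
    dpre2 = dh2 * leaky_relu_grad(cache["pre2"], slope)
    grads["V2"] = cache["h1"].T @ dpre2
    grads["c2"] = dpre2.sum(axis=0)
    dh1 = dpre2 @ c["V2"].T
    dpre1 = dh1 * leaky_relu_grad(cache["pre1"], slope)
    grads["V1"] = x.T @ dpre1
    grads["c1"] = dpre1.sum(axis=0)
    return grads


def penalty_and_param_grads(ensemble: CriticEnsemble, j: int, s: np.ndarray) -> tuple:
    """Mean (||grad_s W_j(s)||_2 - 1)^2 over rows, and its parameter gradients.

    The input gradient g_r = V1 (d1_r * (V2 (d2_r * v3))) is multilinear in
    (V1, V2, v3) once the activation-derivative diagonals d1, d2 are frozen,
    which is exactly the function autodiff differentiates for piecewise-linear
    activations; biases receive zero gradient from the penalty.
    """
    _check_index(ensemble, j)
    s = np.atleast_2d(np.asarray(s, dtype=float))
    if s.shape[0] == 0:
        raise ValueError("penalty requires at least one interpolated sample")
    c = ensemble.critics[j]
    slope = ensemble.negative_slope
    cache = _forward(c, s, slope)
    n = s.shape[0]
    d2 = leaky_relu_grad(cache["pre2"], slope)       # (n, h2)
    d1 = leaky_relu_grad(cache["pre1"], slope)       # (n, h1)
    q = d2 * c["v3"].ravel()                         # (n, h2)
    t = d1 * (q @ c["V2"].T)                         # (n, h1)
    g = t @ c["V1"].T                                # (n, p)

    norms = np.linalg.norm(g, axis=1)
    value = float(np.mean((norms - 1.0) ** 2))

    # dP/dg_r = (2/n) (||g_r|| - 1) g_r / ||g_r||; zero where the norm is 0
    safe = np.where(norms > 0, norms, 1.0)
    coef = np.where(norms > 0, (2.0 / n) * (norms - 1.0) / safe, 0.0)
    e = coef[:, None] * g                            # (n, p)

    grads = {k: np.zeros_like(v) for k, v in c.items()}
    grads["V1"] = e.T @ t                            # (p, h1)
    a = e @ c["V1"]                                  # (n, h1) = dP/dt
    ad1 = a * d1
    grads["V2"] = ad1.T @ q                          # (h1, h2)
    b = ad1 @ c["V2"]                                # (n, h2) = dP/dq
    grads["v3"] = (b * d2).sum(axis=0)[:, None]      # (h2, 1)
    return value, grads
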