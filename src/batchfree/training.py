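"""Two-step adversarial training and the integration entry point.

Step 1 pretrains the critic ensemble on the uncorrected batches (the
corrector is bypassed), so each critic starts as a useful estimate of the
batch-vs-rest Wasserstein distance.  Step 2 alternates: several critic
updates (each critic ascends its own Wasserstein estimate while paying the
gradient penalty) followed by one corrector update (descending the summed
estimates).  Mini-batches are sampled independently per batch with
replacement, which balances unequal batch sizes.

All randomness flows from a single seeded generator, so identical configs
give identical runs in single-threaded execution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam
from .containers import BatchCollection
from .corrector import (
    CorrectorParams,
    apply_full,
    correct_cells,
    corrector_backward,
    init_corrector,
)
from .critic import (
    CriticEnsemble,
    critic_input_gradient,
    critic_param_grads,
    critic_score,
    init_critics,
    penalty_and_param_grads,
)
from .objective import ObjectiveConfig, pair_coefficient, pair_interpolants


@dataclass
class TrainConfig:
    minibatch_size: int = 128
    pretrain_steps: int = 200
    main_steps: int = 2000
    critic_steps_per_corrector_step: int = 5
    lr_corrector: float = 1e-4
    lr_critic: float = 1e-4
    optimizer: str = "adam"
    seed: int = 0
    corrector_hidden: tuple = (256, 256)
    critic_hidden: tuple = (256, 64)
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)

    def __post_init__(self) -> None:
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be >= 1")
        if self.pretrain_steps < 0 or self.main_steps < 0:
            raise ValueError("step counts must be non-negative")
        if self.critic_steps_per_corrector_step < 1:
            raise ValueError("critic_steps_per_corrector_step must be >= 1")
        if self.lr_corrector <= 0 or self.lr_critic <= 0:
            raise ValueError("learning rates must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["objective"] = self.objective.to_dict()
        d["corrector_hidden"] = list(self.corrector_hidden)
        d["critic_hidden"] = list(self.critic_hidden)
        return d


@dataclass
class TrainLog:
    history: list
    seed: int
    config: dict

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        rows = []
        for step, rec in enumerate(self.history):
            row = {"step": step, "phase": rec["phase"],
                   "penalty": rec["penalty_total"], "total": rec["total"]}
            for j, v in enumerate(rec["per_critic"]):
                row[f"critic_{j}"] = v
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def sample_minibatches(collection: BatchCollection, size: int,
                       rng: np.random.Generator, replace: bool = True) -> list:
    """One uniform sample of ``size`` cells from every batch."""
    if size < 1:
        raise ValueError("size must be >= 1")
    out = []
    for i in range(collection.n_batches):
        n = collection.matrices[i].shape[0]
        if n == 0:
            raise ValueError(f"batch {collection.batch_names[i]!r} is empty")
        if replace:
            idx = rng.integers(0, n, size=size)
        else:
            if size > n:
                raise ValueError(f"cannot draw {size} cells without replacement from {n}")
            idx = rng.permutation(n)[:size]
        out.append(collection.dense(i)[idx])
    return out


def _make_optimizers(params_list: list, lr: float, kind: str) -> list:
    if kind == "adam":
        return [Adam(p, lr=lr) for p in params_list]
    return [None] * len(params_list)  # plain SGD carries no state


def _sgd_step(params: dict, grads: dict, lr: float) -> None:
    for k, g in grads.items():
        params[k] -= lr * g


def _check_finite(value: float, step: int, term: str) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss at step {step} in term {term!r}")


def _critic_update(ensemble: CriticEnsemble, corrected: list, cfg: TrainConfig,
                   opts: list, rng: np.random.Generator, step: int):
    """One gradient step per critic: ascend L_w^j, descend the penalty.

    Returns (per-critic Wasserstein estimates, total penalty) at the
    pre-update parameters for logging.
    """
    M = ensemble.n_batches
    lam = cfg.objective.lambda_gp
    per_critic = np.zeros(M)
    penalty_total = 0.0
    sizes = [np.atleast_2d(c).shape[0] for c in corrected]
    for j in range(M):
        grads = {k: np.zeros_like(v) for k, v in ensemble.critics[j].items()}
        est = 0.0
        for i in range(M):
            f = pair_coefficient(i, j, M)
            scores = critic_score(ensemble, j, corrected[i])
            est += f * float(np.mean(scores))
            # critic minimizes -L_w^j: weight per score is -f/n_i
            w = np.full(sizes[i], -f / sizes[i])
            for k, g in critic_param_grads(ensemble, j, corrected[i], w).items():
                grads[k] += g
        for i in range(M):
            if i == j and not cfg.objective.include_diagonal_pairs:
                continue
            s = pair_interpolants(corrected, i, j, cfg.objective, rng)
            val, pgrads = penalty_and_param_grads(ensemble, j, s)
            penalty_total += val
            for k, g in pgrads.items():
                grads[k] += lam * g
        per_critic[j] = est
        _check_finite(est, step, f"wasserstein term j={j}")
        if cfg.optimizer == "adam":
            opts[j].step(ensemble.critics[j], grads)
        else:
            _sgd_step(ensemble.critics[j], grads, cfg.lr_critic)
    _check_finite(penalty_total, step, "gradient penalty")
    return per_critic, penalty_total


def _corrector_update(corrector: CorrectorParams, ensemble: CriticEnsemble,
                      raw: list, cfg: TrainConfig, opt, step: int) -> None:
    """One corrector step descending sum_j L_w^j (penalty excluded)."""
    M = ensemble.n_batches
    grads = {k: np.zeros_like(v) for k, v in corrector.params.items()}
    for i in range(M):
        out = correct_cells(raw[i], i, corrector, keep_cache=True)
        n = out.corrected.shape[0]
        d_corrected = np.zeros_like(out.corrected)
        for j in range(M):
            f = pair_coefficient(i, j, M)
            d_corrected += (f / n) * critic_input_gradient(ensemble, j, out.corrected)
        for k, g in corrector_backward(out, corrector, d_corrected).items():
            grads[k] += g
    for k in grads:
        _check_finite(float(np.sum(grads[k])), step, f"corrector grad {k}")
    if cfg.optimizer == "adam":
        opt.step(corrector.params, grads)
    else:
        _sgd_step(corrector.params, grads, cfg.lr_corrector)


def pretrain_critics(collection: BatchCollection, ensemble: CriticEnsemble,
                     cfg: TrainConfig, rng: np.random.Generator):
    """Critic-only updates on the uncorrected data (corrector bypassed)."""
    opts = _make_optimizers([c for c in ensemble.critics], cfg.lr_critic, cfg.optimizer)
    history = []
    for step in range(cfg.pretrain_steps):
        raw = sample_minibatches(collection, cfg.minibatch_size, rng)
        per_critic, penalty = _critic_update(ensemble, raw, cfg, opts, rng, step)
        history.append({
            "phase": "pretrain",
            "per_critic": per_critic.tolist(),
            "penalty_total": penalty,
            "total": float(np.sum(per_critic) + cfg.objective.lambda_gp * penalty),
        })
    return ensemble, history, opts


def train(collection: BatchCollection, cfg: TrainConfig):
    """Full two-step training; returns (corrector, ensemble, log)."""
    if collection.scale != "lognorm":
        raise ValueError("training expects a log-normalized collection")
    M = collection.n_batches
    p = collection.n_genes
    rng = np.random.default_rng(cfg.seed)
    corrector = init_corrector(p, cfg.corrector_hidden, M, seed=cfg.seed)
    ensemble = init_critics(p, cfg.critic_hidden, M, seed=cfg.seed + 1)

    ensemble, history, critic_opts = pretrain_critics(collection, ensemble, cfg, rng)
    corr_opt = _make_optimizers([corrector.params], cfg.lr_corrector, cfg.optimizer)[0]

    for step in range(cfg.main_steps):
        per_critic = np.zeros(M)
        penalty = 0.0
        for _ in range(cfg.critic_steps_per_corrector_step):
            raw = sample_minibatches(collection, cfg.minibatch_size, rng)
            corrected = [correct_cells(mb, i, corrector).corrected
                         for i, mb in enumerate(raw)]
            per_critic, penalty = _critic_update(
                ensemble, corrected, cfg, critic_opts, rng, step)
        raw = sample_minibatches(collection, cfg.minibatch_size, rng)
        _corrector_update(corrector, ensemble, raw, cfg, corr_opt, step)
        history.append({
            "phase": "main",
            "per_critic": per_critic.tolist(),
            "penalty_total": penalty,
            "total": float(np.sum(per_critic) + cfg.objective.lambda_gp * penalty),
        })

    log = TrainLog(history, cfg.seed, cfg.to_dict())
    return corrector, ensemble, log


def integrate(collection: BatchCollection, cfg: TrainConfig,
              block_size: int = 2048) -> BatchCollection:
    """Train, then correct every cell; provenance lands in ``meta``."""
    corrector, ensemble, log = train(collection, cfg)
    out = apply_full(collection, corrector, block_size)
    cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
    out.meta.update({
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": hex(abs(hash(cfg_json))),
    })
    return out


def save_checkpoint(path: str, corrector: CorrectorParams,
                    ensemble: CriticEnsemble) -> None:
    """Single archive with named arrays plus a JSON header of dims and seeds."""
    arrays = {f"corrector/{k}": v for k, v in corrector.params.items()}
    for j, c in enumerate(ensemble.critics):
        arrays.update({f"critic{j}/{k}": v for k, v in c.items()})
    header = {
        "schema": 1,
        "input_dim": corrector.input_dim,
        "corrector_hidden": list(corrector.hidden_dims),
        "critic_hidden": list(ensemble.hidden_dims),
        "n_batches": corrector.n_batches,
        "negative_slope": corrector.negative_slope,
        "seed": corrector.seed,
    }
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str):
    data = np.load(path)
    header = json.loads(bytes(data["header"]).decode())
    cparams = {k.split("/", 1)[1]: data[k] for k in data.files if k.startswith("corrector/")}
    corrector = CorrectorParams(
        cparams, header["input_dim"], tuple(header["corrector_hidden"]),
        header["n_batches"], header["negative_slope"], header["seed"],
    )
    critics = []
    for j in range(header["n_batches"]):
        critics.append({k.split("/", 1)[1]: data[k] for k in data.files
                        if k.startswith(f"critic{j}/")})
    ensemble = CriticEnsemble(
        critics, header["input_dim"], tuple(header["critic_hidden"]),
        header["negative_slope"], header["seed"],
    )
    return corrector, ensemble
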