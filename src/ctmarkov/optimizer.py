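"""Mini-batch stochastic gradient ascent for the CTMM log-likelihood.

The update at step ``d`` is::

    theta_{d+1} = theta_d + lambda_{d+1} * (M / |B_d|) * sum_{m in B_d} score_m(theta_d)

with ``B_d`` a random subject mini-batch and learning rate
``lambda_{d+1} = lr_scale * (d+1)^(-lr_exponent)``.  The ``M/|B|`` factor
makes the mini-batch gradient an unbiased estimate of the full-data
gradient, so with ``|B| = M`` the update is plain full-gradient ascent.

The likelihood is not globally concave; multiple restarts from random
initializations are used and the restart with the highest full-data
log-likelihood wins.  Optimization defaults to the ``log_q0`` scale so the
baseline intensities stay positive no matter the step size.

On the magnitude of ``lr_scale``: the summed gradient grows linearly with
the number of observation intervals, so a scale of order ``1 / n_intervals``
keeps the first steps of order one.  :func:`suggested_lr_scale` encodes that
rule of thumb; the default ``lr_scale=1.0`` matches the schedule's textbook
form and is appropriate when the caller has pre-scaled or the dataset is
tiny.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .likelihood import PanelDataset, dataset_loglik, dataset_score
from .model import (
    TRANSITION_DEPENDENT,
    ParameterSet,
    TransitionStructure,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "learning_rate",
    "minibatch_step",
    "init_parameters",
    "suggested_lr_scale",
    "fit",
]

#: numerical guard: |log q0| and |beta| are clipped here after each step to
#: keep intermediate exponentials representable; the bound is far outside
#: any scientifically meaningful rate or log hazard ratio
_THETA_CLIP = 50.0


@dataclass(frozen=True)
class FitConfig:
    """Settings for the stochastic-gradient fit.

    batch_size
        Subjects per mini-batch (clipped to M).  500 is a good default for
        large panels; with ``batch_size >= M`` every step uses the full
        gradient.
    lr_exponent, lr_scale
        Learning rate ``lr_scale * (d+1)^(-lr_exponent)``.
    max_iters
        Step budget per restart.
    tol
        Convergence threshold on the sup-norm parameter change, averaged
        over the trailing 5 steps (raw per-step SGD changes oscillate).
    restarts
        Number of random initializations; 1000-5000 is advised for
        full-scale studies, far fewer suffice for small well-identified
        models.
    max_step
        Sup-norm cap on a single update (the step is rescaled, keeping its
        direction).  One unit on the log-intensity / log-hazard-ratio
        scale is far beyond any sensible single move; the cap prevents a
        noisy early mini-batch from catapulting the iterate into a flat
        degenerate region.
    init_policy
        ``distance_decay_normal`` (default), ``warmstart_subsample`` or
        ``user`` (supply ``theta0``).
    sampling
        ``without_replacement_epochs`` (shuffled epochs, default) or
        ``with_replacement``.
    """

    batch_size: int = 500
    lr_exponent: float = 0.6
    lr_scale: float = 1.0
    max_iters: int = 500
    tol: float = 1e-6
    restarts: int = 1000
    init_policy: str = "distance_decay_normal"
    sampling: str = "without_replacement_epochs"
    max_step: float = 1.0
    scale: str = "log_q0"
    seed: int | None = None
    trace_loglik_every: int = 25
    validation_subjects: int = 200

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.sampling not in ("without_replacement_epochs", "with_replacement"):
            raise ValueError(f"unknown sampling {self.sampling!r}")


@dataclass
class FitResult:
    """Outcome of a multi-restart fit."""

    params: ParameterSet
    theta_hat: np.ndarray
    scale: str
    loglik: float
    converged: bool
    n_iters: int
    restart_index: int
    trace: list = field(default_factory=list)
    restart_logliks: list = field(default_factory=list)
    init_loglik: float = np.nan


def learning_rate(d: int, lr_exponent: float = 0.6, lr_scale: float = 1.0) -> float:
    """Decaying learning rate ``lr_scale * (d+1)^(-lr_exponent)`` at step ``d >= 0``."""
    if d < 0:
        raise ValueError("iteration index must be nonnegative")
    return lr_scale * float(d + 1) ** (-lr_exponent)


def suggested_lr_scale(dataset: PanelDataset) -> float:
    """Rule-of-thumb ``lr_scale``: one over the total interval count."""
    return 1.0 / max(dataset.n_intervals, 1)


def minibatch_step(
    theta: np.ndarray,
    batch: np.ndarray,
    d: int,
    dataset: PanelDataset,
    structure: TransitionStructure,
    covariate_names: Sequence[str],
    config: FitConfig,
    mode: str = TRANSITION_DEPENDENT,
) -> tuple[np.ndarray, float]:
    """One ascent step on a subject mini-batch.

    Returns the updated theta and the sup-norm of the accepted step.  A
    non-finite gradient (degenerate batch) triggers up to 5 learning-rate
    halvings before the batch is skipped.
    """
    batch = np.asarray(batch, dtype=int)
    if batch.size == 0:
        raise ValueError("mini-batch must be non-empty")
    params = ParameterSet.from_theta(
        theta, structure, covariate_names, mode=mode, scale=config.scale
    )
    grad = dataset_score(
        params, dataset, scale=config.scale, subject_indices=batch
    )
    scaling = dataset.M / batch.size
    lr = learning_rate(d, config.lr_exponent, config.lr_scale)
    for _ in range(6):
        step = lr * scaling * grad
        if np.all(np.isfinite(step)):
            norm = np.abs(step).max()
            if config.max_step and norm > config.max_step:
                step = step * (config.max_step / norm)
            new = np.clip(theta + step, -_THETA_CLIP, _THETA_CLIP)
            return new, float(np.abs(new - theta).max())
        lr *= 0.5
    return theta, 0.0  # skip the batch


def init_parameters(
    policy: str,
    dataset: PanelDataset,
    seed,
    structure: TransitionStructure,
    mode: str = TRANSITION_DEPENDENT,
    scale: str = "log_q0",
    theta0: np.ndarray | None = None,
    warmstart_subjects: int = 500,
) -> np.ndarray:
    """Draw an initial flat parameter vector.

    ``distance_decay_normal``
        Baseline intensity for transition ``i -> j`` from the positive part
        of ``Normal(1/|i-j|, 1/|i-j|)`` (redrawn until positive): nearby
        states start with larger rates.  Betas from ``Uniform(-1, 1)``.
    ``warmstart_subsample``
        One deterministic full-gradient run on a subject subsample; its
        optimum seeds the restarts.
    ``user``
        Pass-through of ``theta0`` (on ``scale``).
    """
    rng = np.random.default_rng(seed)
    cov = dataset.covariate_names
    if policy == "user":
        if theta0 is None:
            raise ValueError("policy 'user' requires theta0")
        return np.asarray(theta0, dtype=float).copy()
    if policy == "distance_decay_normal":
        q0 = np.empty(structure.n_transitions)
        for t, (i, j) in enumerate(structure.pairs):
            m = 1.0 / abs(i - j)
            draw = rng.normal(m, m)
            while draw <= 0:
                draw = rng.normal(m, m)
            q0[t] = draw
        R = len(cov)
        if mode == TRANSITION_DEPENDENT:
            beta = rng.uniform(-1, 1, (structure.n_transitions, R))
        else:
            beta = rng.uniform(-1, 1, R)
        return ParameterSet(
            structure, q0, beta, mode=mode, covariate_names=cov
        ).to_theta(scale)
    if policy == "warmstart_subsample":
        sub_idx = np.arange(min(warmstart_subjects, dataset.M))
        sub = PanelDataset(
            [dataset.trajectories[i] for i in sub_idx],
            dataset.state_space,
            cov,
            centering=dataset.centering,
        )
        cfg = FitConfig(
            batch_size=sub.M,
            lr_scale=suggested_lr_scale(sub),
            max_iters=300,
            restarts=1,
            init_policy="distance_decay_normal",
            scale=scale,
            seed=int(rng.integers(2**31 - 1)),
        )
        return fit(sub, cfg, structure=structure, mode=mode).theta_hat
    raise ValueError(f"unknown init policy {policy!r}")


def _batch_stream(M: int, batch_size: int, sampling: str, rng: np.random.Generator):
    """Yield mini-batches forever."""
    b = min(batch_size, M)
    if sampling == "with_replacement":
        while True:
            yield rng.choice(M, size=b, replace=False)
    else:  # shuffled epochs, without replacement within an epoch
        while True:
            order = rng.permutation(M)
            for lo in range(0, M - b + 1, b):
                yield order[lo : lo + b]


def fit(
    dataset: PanelDataset,
    config: FitConfig | None = None,
    structure: TransitionStructure | None = None,
    mode: str = TRANSITION_DEPENDENT,
    theta0: np.ndarray | None = None,
) -> FitResult:
    """Maximum-likelihood fit by mini-batch stochastic gradient ascent.

    Each restart iterates :func:`minibatch_step` until the trailing-average
    parameter change drops below ``config.tol`` or ``max_iters`` is reached;
    the restart with the highest full-data log-likelihood wins.

    ``structure`` defaults to every ordered pair observed in adjacent
    visits of the dataset.
    """
    if config is None:
        config = FitConfig()
    if structure is None:
        from .evaluation import transition_frequency_filter

        structure = transition_frequency_filter(dataset, threshold=0.0)
    _warn_unobserved(dataset, structure)

    root = np.random.default_rng(config.seed)
    M = dataset.M
    val_idx = np.sort(
        root.choice(M, size=min(config.validation_subjects, M), replace=False)
    )

    best: FitResult | None = None
    restart_lls = []
    for r in range(config.restarts):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        theta = init_parameters(
            config.init_policy,
            dataset,
            rng.integers(2**31 - 1),
            structure,
            mode=mode,
            scale=config.scale,
            theta0=theta0,
        )
        init_params = ParameterSet.from_theta(
            theta, structure, dataset.covariate_names, mode=mode, scale=config.scale
        )
        init_ll = dataset_loglik(init_params, dataset)
        trace = []
        recent = []
        converged = False
        n_iters = 0
        batches = _batch_stream(M, config.batch_size, config.sampling, rng)
        for d in range(config.max_iters):
            batch = next(batches)
            theta, step_norm = minibatch_step(
                theta, batch, d, dataset, structure, dataset.covariate_names, config, mode
            )
            n_iters = d + 1
            recent.append(step_norm)
            if len(recent) > 5:
                recent.pop(0)
            val_ll = None
            if config.trace_loglik_every and (d % config.trace_loglik_every == 0):
                pv = ParameterSet.from_theta(
                    theta, structure, dataset.covariate_names, mode=mode, scale=config.scale
                )
                if M <= len(val_idx):
                    val_ll = dataset_loglik(pv, dataset)
                else:
                    val_ll = _subset_loglik(pv, dataset, val_idx)
            trace.append((d, val_ll, step_norm))
            if len(recent) == 5 and np.mean(recent) < config.tol:
                converged = True
                break
        params_hat = ParameterSet.from_theta(
            theta, structure, dataset.covariate_names, mode=mode, scale=config.scale
        )
        ll = dataset_loglik(params_hat, dataset)
        restart_lls.append(ll)
        if not np.isfinite(ll):
            continue
        if best is None or ll > best.loglik:
            best = FitResult(
                params=params_hat,
                theta_hat=theta,
                scale=config.scale,
                loglik=ll,
                converged=converged,
                n_iters=n_iters,
                restart_index=r,
                trace=trace,
                init_loglik=init_ll,
            )
    if best is None:
        raise RuntimeError(
            f"all {config.restarts} restarts produced non-finite likelihoods; "
            f"restart log-likelihoods: {restart_lls}"
        )
    best.restart_logliks = restart_lls
    return best


def _subset_loglik(params, dataset, idx) -> float:
    from .likelihood import _Intervals, _loglik_terms, _interval_probabilities

    ivs = dataset.intervals
    mask = np.isin(ivs.subject, idx)
    sub = _Intervals(ivs.tau[mask], ivs.frm[mask], ivs.to[mask], ivs.Z[mask], ivs.subject[mask])
    p = _interval_probabilities(params, sub)
    terms, _ = _loglik_terms(p)
    return float(terms.sum())


def _warn_unobserved(dataset: PanelDataset, structure: TransitionStructure) -> None:
    ivs = dataset.intervals
    observed = set(zip(ivs.frm.tolist(), ivs.to.tolist()))
    missing = [p for p in structure.pairs if p not in observed]
    if missing:
        warnings.warn(
            f"no adjacent-visit observation for modelled transitions {missing}; "
            "their parameters are weakly identified",
            stacklevel=3,
        )
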