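"""Synthetic panel data from a covariate-modulated CTMM.

The generator emulates a long-term observational study: each subject's
underlying state evolves as a continuous-time Markov chain whose
intensities depend on the subject's current covariates, and the chain is
*observed* only at scheduled visits every ``dummy_interval`` time units up
to a horizon ``t_max`` — the interval-censored panel the likelihood is
written for.  Covariates are redrawn at every visit (time-varying ones)
and carried forward, so the intensities are piecewise constant between
visits, exactly matching the likelihood's carry-forward convention.

Per subject:

1. draw initial covariates, build the generator ``Q``, and draw the
   initial state from its stationary distribution (solve ``pi^T Q = 0``);
2. evolve the latent chain exactly (Gillespie): in state ``s`` the sojourn
   is exponential with rate ``-q_ss``, and at a jump the next state comes
   from the embedded jump chain ``Pr(j) = q_sj / (-q_ss)``;
3. at each scheduled visit, record the current state together with
   freshly drawn covariates, rebuild the generator, and continue;
4. stop at ``t_max``.

Two readings of the next-state draw are supported: the embedded jump
chain (exact, default) and ``next_state_law="transition_probability"``,
which draws the destination from the row of ``Exp(Q * sojourn)`` restricted
to other states.

``observe_jumps=True`` additionally emits an observation at the exact time
of every state change.  This makes the visit times informative (a visit
happens *because* a transition happened), which the interval-censored
likelihood does not model; fitting such data noticeably inflates the
estimated intensities.  The flag exists to study that effect — the default
panel is observed on the non-informative schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .likelihood import Observation, PanelDataset, Trajectory
from .model import (
    ParameterSet,
    StateSpace,
    build_intensity_matrix,
    stationary_distribution,
    transition_probability,
)

__all__ = ["SimConfig", "simulate_path", "simulate_subject", "simulate_dataset"]


def _default_covariate_law(rng: np.random.Generator, size: int) -> np.ndarray:
    """Uniform draws centered at zero."""
    return rng.uniform(-0.5, 0.5, size)


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Parameters
    ----------
    M
        Number of subjects.
    params
        True model: structure, baseline intensities and covariate effects.
    t_max
        Follow-up horizon (time units of the study, e.g. years).
    dummy_interval
        Spacing of scheduled visits.  1/3 to 1/2 of a year mirrors the
        4-6-monthly clinical assessment cadence of MS trials.
    covariate_law
        Sampler ``f(rng, size) -> draws``; default uniform centered at zero.
    time_varying
        Per-covariate flags; a ``False`` entry is drawn once per subject
        and held fixed (e.g. sex).  Default: all time-varying.
    next_state_law
        ``"embedded"`` (exact, default) or ``"transition_probability"``.
    observe_jumps
        Also emit an observation at each exact jump time (informative
        visit scheme; see module docstring).  Default off.
    seed
        Root seed; each subject gets an independently spawned stream, so
        the dataset is reproducible regardless of execution order.
    """

    M: int
    params: ParameterSet
    t_max: float = 15.0
    dummy_interval: float = 1.0 / 3.0
    covariate_law: Callable[[np.random.Generator, int], np.ndarray] = field(
        default=_default_covariate_law
    )
    time_varying: Sequence[bool] | None = None
    next_state_law: str = "embedded"
    observe_jumps: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.t_max <= 0 or self.dummy_interval <= 0:
            raise ValueError("t_max and dummy_interval must be positive")
        if self.next_state_law not in ("embedded", "transition_probability"):
            raise ValueError(f"unknown next_state_law {self.next_state_law!r}")
        if self.time_varying is None:
            self.time_varying = tuple([True] * self.params.R)
        else:
            self.time_varying = tuple(bool(v) for v in self.time_varying)
            if len(self.time_varying) != self.params.R:
                raise ValueError("time_varying must have one flag per covariate")


def _next_state(
    Q: np.ndarray, state: int, sojourn: float, rng: np.random.Generator, law: str
) -> int:
    if law == "embedded":
        probs = np.clip(Q[state], 0.0, None)
        probs[state] = 0.0
    else:
        probs = transition_probability(Q, sojourn)[state].copy()
        probs[state] = 0.0
        if probs.sum() <= 0:
            probs = np.clip(Q[state], 0.0, None)
            probs[state] = 0.0
    return int(rng.choice(Q.shape[0], p=probs / probs.sum()))


def simulate_path(
    Q: np.ndarray,
    rng: np.random.Generator,
    t_max: float,
    initial_state: int | None = None,
    next_state_law: str = "embedded",
) -> tuple[np.ndarray, np.ndarray]:
    """Exact jump path of a fixed-generator chain up to ``t_max``.

    Returns ``(times, states)`` with ``times[0] = 0`` and one entry per
    jump thereafter; the chain holds ``states[-1]`` from ``times[-1]`` to
    ``t_max``.  Used by the observation layer and directly by
    distributional tests (sojourn means, embedded-chain frequencies).
    """
    if initial_state is None:
        initial_state = int(rng.choice(Q.shape[0], p=stationary_distribution(Q)))
    times, states = [0.0], [initial_state]
    t, s = 0.0, initial_state
    while True:
        rate = -Q[s, s]
        if rate <= 0:
            break
        sojourn = rng.exponential(1.0 / rate)
        if t + sojourn >= t_max:
            break
        t += sojourn
        s = _next_state(Q, s, sojourn, rng, next_state_law)
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states, dtype=int)


def _draw_covariates(
    config: SimConfig, rng: np.random.Generator, fixed: np.ndarray
) -> np.ndarray:
    z = np.array(fixed, dtype=float)
    tv = np.asarray(config.time_varying, dtype=bool)
    if tv.any():
        z[tv] = config.covariate_law(rng, int(tv.sum()))
    return z


def simulate_subject(
    config: SimConfig, rng: np.random.Generator, subject_id="s0"
) -> Trajectory:
    """Simulate one subject's observed trajectory."""
    params = config.params
    R = params.R
    fixed = config.covariate_law(rng, R) if R else np.zeros(0)
    z = _draw_covariates(config, rng, fixed)
    Q = build_intensity_matrix(params, z)
    pi = stationary_distribution(Q)
    state = int(rng.choice(Q.shape[0], p=pi))

    obs = [Observation(0.0, state, z)]
    t = 0.0
    eps = 1e-12 * max(config.t_max, 1.0)
    next_visit = config.dummy_interval
    while next_visit <= config.t_max + eps:
        # evolve the latent chain across (t, next_visit]; the generator is
        # rebuilt within the interval only when the *state* changes — the
        # covariates in force are those from the last visit
        while True:
            rate = -Q[state, state]
            if rate <= 0:
                break
            sojourn = rng.exponential(1.0 / rate)
            if t + sojourn >= next_visit:
                break
            t += sojourn
            state = _next_state(Q, state, sojourn, rng, config.next_state_law)
            if config.observe_jumps:
                z = _draw_covariates(config, rng, fixed)
                obs.append(Observation(t, state, z))
            Q = build_intensity_matrix(params, z)
        t = next_visit
        z = _draw_covariates(config, rng, fixed)
        obs.append(Observation(t, state, z))
        Q = build_intensity_matrix(params, z)
        next_visit += config.dummy_interval
    return Trajectory(subject_id, obs)


def simulate_dataset(config: SimConfig) -> PanelDataset:
    """Simulate ``M`` independent subjects into a panel dataset."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.M)
    space = StateSpace.of_size(config.params.structure.S)
    names = config.params.covariate_names or tuple(
        f"z{r}" for r in range(config.params.R)
    )
    trajectories = [
        simulate_subject(config, np.random.default_rng(child), subject_id=f"s{m}")
        for m, child in enumerate(children)
    ]
    return PanelDataset(trajectories, space, covariate_names=names)
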