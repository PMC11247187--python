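"""State spaces, parameter containers, and transition-intensity matrices.

A continuous-time Markov multistate model on ``S`` states is characterized
by a generator (transition-intensity) matrix ``Q``: off-diagonal ``q_ij`` is
the instantaneous rate of moving from state ``i`` to state ``j``, and each
diagonal entry is minus the corresponding row sum, so rows sum to zero.
Covariates act multiplicatively on the intensities through a proportional
hazards form::

    q_ij(z) = q0_ij * exp(sum_r z_r * beta_ij_r)

where ``q0_ij`` is the baseline intensity (all covariates at zero / their
reference) and ``beta_ij_r`` the log-hazard-ratio of covariate ``r`` on the
``i -> j`` transition.  Over an elapsed time ``tau`` the transition
probabilities are ``P(tau) = Exp(Q * tau)`` (Kolmogorov relation for the
time-homogeneous chain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._expm import expm

__all__ = [
    "StateSpace",
    "TransitionStructure",
    "ParameterSet",
    "build_intensity_matrix",
    "transition_probability",
    "stationary_distribution",
    "validate_generator",
]

TRANSITION_DEPENDENT = "transition_dependent"
TRANSITION_INDEPENDENT = "transition_independent"

#: tolerance for generator row sums
_ROWSUM_TOL = 1e-10


@dataclass(frozen=True)
class StateSpace:
    """Ordered finite state space with external labels.

    Internally all linear algebra uses contiguous 0-based indices; external
    labels (e.g. EDSS levels 0..8) are mapped at the boundary.
    """

    labels: tuple

    def __init__(self, labels: Iterable):
        labels = tuple(labels)
        if len(labels) < 2:
            raise ValueError("a state space needs at least 2 states")
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique")
        object.__setattr__(self, "labels", labels)

    @property
    def S(self) -> int:
        return len(self.labels)

    @property
    def index_map(self) -> dict:
        return {lab: i for i, lab in enumerate(self.labels)}

    def to_index(self, label):
        try:
            return self.index_map[label]
        except KeyError:
            raise KeyError(f"unknown state label {label!r}; known: {self.labels}")

    def to_label(self, index: int):
        return self.labels[index]

    @classmethod
    def of_size(cls, S: int) -> "StateSpace":
        return cls(range(S))


@dataclass(frozen=True)
class TransitionStructure:
    """The set of ordered state pairs whose intensity is modelled.

    Every off-diagonal pair not listed is structurally zero and carries no
    parameter at all (it is excluded from the parameter vector).
    """

    S: int
    pairs: tuple

    def __init__(self, S: int, pairs: Iterable[tuple]):
        pairs = tuple((int(i), int(j)) for i, j in pairs)
        for i, j in pairs:
            if i == j:
                raise ValueError(f"diagonal pair ({i},{i}) is not a transition")
            if not (0 <= i < S and 0 <= j < S):
                raise ValueError(f"pair ({i},{j}) outside state range 0..{S - 1}")
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate transition pairs")
        object.__setattr__(self, "S", int(S))
        object.__setattr__(self, "pairs", pairs)

    @property
    def n_transitions(self) -> int:
        return len(self.pairs)

    @property
    def rows(self) -> np.ndarray:
        return np.array([i for i, _ in self.pairs], dtype=int)

    @property
    def cols(self) -> np.ndarray:
        return np.array([j for _, j in self.pairs], dtype=int)

    @classmethod
    def full(cls, S: int) -> "TransitionStructure":
        return cls(S, [(i, j) for i in range(S) for j in range(S) if i != j])

    @classmethod
    def adjacent(cls, S: int, width: int = 1) -> "TransitionStructure":
        """Band structure: transitions with ``|i - j| <= width`` (both directions)."""
        return cls(
            S,
            [
                (i, j)
                for i in range(S)
                for j in range(S)
                if i != j and abs(i - j) <= width
            ],
        )

    @classmethod
    def from_matrix(cls, Q0: np.ndarray) -> "TransitionStructure":
        """Pairs with a strictly positive off-diagonal entry in ``Q0``."""
        Q0 = np.asarray(Q0, dtype=float)
        S = Q0.shape[0]
        return cls(S, [(i, j) for i in range(S) for j in range(S) if i != j and Q0[i, j] > 0])


@dataclass
class ParameterSet:
    """Baseline intensities and regression coefficients for a CTMM.

    Parameters
    ----------
    structure
        Which ordered transitions carry parameters.
    q0
        Baseline intensity per transition, in structure order; nonnegative,
        units of events per unit time.
    beta
        Covariate effects.  Shape ``(n_transitions, R)`` in
        transition-dependent mode (each covariate has its own effect per
        transition) or ``(R,)`` in transition-independent mode (one common
        effect across all transitions).
    mode
        ``"transition_dependent"`` or ``"transition_independent"``.
    covariate_names
        Length-``R`` covariate labels.

    The flat parameter vector ("theta") layout is deterministic:
    transition-major in dependent mode — for each transition ``t`` in
    structure order, ``q0_t`` followed by its ``R`` betas; in independent
    mode all ``q0`` first, then the ``R`` shared betas.  On the ``log_q0``
    scale the baseline entries are ``log q0`` and the vector is fully
    unconstrained.
    """

    structure: TransitionStructure
    q0: np.ndarray
    beta: np.ndarray
    mode: str = TRANSITION_DEPENDENT
    covariate_names: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self):
        self.q0 = np.asarray(self.q0, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        T = self.structure.n_transitions
        R = len(self.covariate_names)
        if self.q0.shape != (T,):
            raise ValueError(f"q0 must have shape ({T},), got {self.q0.shape}")
        if np.any(self.q0 < 0):
            raise ValueError("baseline intensities must be nonnegative")
        if self.mode == TRANSITION_DEPENDENT:
            want = (T, R)
        elif self.mode == TRANSITION_INDEPENDENT:
            want = (R,)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        if R == 0:
            self.beta = self.beta.reshape(want)
        if self.beta.shape != want:
            raise ValueError(f"beta must have shape {want}, got {self.beta.shape}")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        self.covariate_names = tuple(self.covariate_names)

    @property
    def R(self) -> int:
        return len(self.covariate_names)

    @property
    def n_params(self) -> int:
        T = self.structure.n_transitions
        return T * (1 + self.R) if self.mode == TRANSITION_DEPENDENT else T + self.R

    # -- flat theta ---------------------------------------------------------
    def to_theta(self, scale: str = "log_q0") -> np.ndarray:
        q = self.q0
        if scale == "log_q0":
            with np.errstate(divide="ignore"):
                q = np.log(self.q0)
        elif scale != "raw":
            raise ValueError(f"unknown scale {scale!r}")
        if self.mode == TRANSITION_DEPENDENT:
            return np.concatenate([q[:, None], self.beta], axis=1).ravel()
        return np.concatenate([q, self.beta])

    @classmethod
    def from_theta(
        cls,
        theta: np.ndarray,
        structure: TransitionStructure,
        covariate_names: Sequence[str],
        mode: str = TRANSITION_DEPENDENT,
        scale: str = "log_q0",
    ) -> "ParameterSet":
        theta = np.asarray(theta, dtype=float)
        T = structure.n_transitions
        R = len(covariate_names)
        if mode == TRANSITION_DEPENDENT:
            if theta.shape != (T * (1 + R),):
                raise ValueError(f"theta must have length {T * (1 + R)}")
            block = theta.reshape(T, 1 + R)
            q, beta = block[:, 0], block[:, 1:].copy()
        else:
            if theta.shape != (T + R,):
                raise ValueError(f"theta must have length {T + R}")
            q, beta = theta[:T], theta[T:].copy()
        if scale == "log_q0":
            q = np.exp(q)
        elif scale != "raw":
            raise ValueError(f"unknown scale {scale!r}")
        return cls(structure, q.copy(), beta, mode=mode, covariate_names=covariate_names)

    def theta_labels(self) -> list[str]:
        """Human-readable name per flat-theta component."""
        labels = []
        if self.mode == TRANSITION_DEPENDENT:
            for i, j in self.structure.pairs:
                labels.append(f"q0[{i}->{j}]")
                labels.extend(f"beta[{i}->{j},{c}]" for c in self.covariate_names)
        else:
            labels.extend(f"q0[{i}->{j}]" for i, j in self.structure.pairs)
            labels.extend(f"beta[{c}]" for c in self.covariate_names)
        return labels

    def beta_matrix(self) -> np.ndarray:
        """Beta broadcast to shape ``(n_transitions, R)`` whatever the mode."""
        if self.mode == TRANSITION_DEPENDENT:
            return self.beta
        return np.broadcast_to(self.beta, (self.structure.n_transitions, self.R))


def intensities(params: ParameterSet, Z: np.ndarray) -> np.ndarray:
    """Covariate-modulated intensities ``q_t(z)`` for a batch of covariates.

    ``Z`` has shape ``(..., R)``; returns shape ``(..., n_transitions)``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[-1] != params.R:
        raise ValueError(
            f"covariate vector has length {Z.shape[-1]}, model expects {params.R}"
        )
    if params.R:
        lin = Z @ params.beta_matrix().T  # (..., T)
    else:
        lin = np.zeros(Z.shape[:-1] + (params.structure.n_transitions,))
    return params.q0 * np.exp(lin)


def assemble_generators(structure: TransitionStructure, q: np.ndarray) -> np.ndarray:
    """Scatter per-transition intensities ``(..., T)`` into generators ``(..., S, S)``."""
    q = np.asarray(q, dtype=float)
    S = structure.S
    Q = np.zeros(q.shape[:-1] + (S, S))
    Q[..., structure.rows, structure.cols] = q
    diag = -Q.sum(axis=-1)
    Q[..., np.arange(S), np.arange(S)] = diag
    return Q


def build_intensity_matrix(params: ParameterSet, z: np.ndarray) -> np.ndarray:
    """Generator matrix ``Q(z)`` for one covariate vector ``z`` of length R."""
    z = np.asarray(z, dtype=float).reshape(-1)
    if z.shape != (params.R,):
        raise ValueError(f"z has length {z.shape[0]}, model expects R={params.R}")
    q = intensities(params, z[None, :])[0]
    return assemble_generators(params.structure, q)


def validate_generator(Q: np.ndarray, tol: float = _ROWSUM_TOL) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("generator must be square")
    off = Q.copy()
    np.fill_diagonal(off, 0.0)
    if np.any(off < 0):
        raise ValueError("off-diagonal intensities must be nonnegative")
    if np.abs(Q.sum(axis=1)).max() > tol * max(1.0, np.abs(Q).max()):
        raise ValueError("generator rows must sum to zero")
    return Q


def transition_probability(Q: np.ndarray, tau: float) -> np.ndarray:
    """Transition-probability matrix ``P(tau) = Exp(Q * tau)``.

    Entries are clipped into ``[0, 1]`` (round-off can leave residues of
    order 1e-15 outside); rows sum to one to within 1e-8.
    """
    if tau < 0:
        raise ValueError("elapsed time tau must be nonnegative")
    Q = validate_generator(Q)
    P = expm(Q * float(tau))
    return np.clip(P, 0.0, 1.0)


def _recurrent_classes(Q: np.ndarray) -> list[np.ndarray]:
    """Strongly connected classes of the support graph with no outgoing edge."""
    S = Q.shape[0]
    adj = csr_matrix((Q > 0).astype(np.int8))
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    closed = []
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        outside = np.setdiff1d(np.arange(S), members)
        if outside.size == 0 or not np.any(Q[np.ix_(members, outside)] > 0):
            closed.append(members)
    return closed


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution ``pi`` solving ``pi^T Q = 0``, ``sum(pi) = 1``.

    For a reducible chain the solution is not unique; a warning is raised
    and the distribution supported on one recurrent class is returned.
    """
    Q = validate_generator(Q)
    S = Q.shape[0]
    classes = _recurrent_classes(Q)
    if len(classes) != 1 or len(classes[0]) != S:
        warnings.warn(
            "generator is reducible: stationary distribution is not unique; "
            "returning the solution on one recurrent class",
            stacklevel=2,
        )
    members = classes[0]
    Qc = Q[np.ix_(members, members)]
    k = len(members)
    # replace one balance equation with the normalization constraint
    A = Qc.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(k)
    b[-1] = 1.0
    try:
        pi_c = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular stationary system: {exc}")
    pi_c = np.clip(pi_c, 0.0, None)
    pi_c /= pi_c.sum()
    pi = np.zeros(S)
    pi[members] = pi_c
    resid = np.abs(pi @ Q).max()
    if resid > 1e-8:
        warnings.warn(f"stationary residual {resid:.2e} exceeds 1e-8", stacklevel=2)
    return pi
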