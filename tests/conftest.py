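import numpy as np
import pytest

from ctmarkov.likelihood import Observation, PanelDataset, Trajectory
from ctmarkov.model import ParameterSet, StateSpace, TransitionStructure


def random_generator(rng, S, scale=1.0):
    """Random irreducible generator with uniform off-diagonal rates."""
    Q = rng.uniform(0.1, scale, (S, S))
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def random_trajectory(rng, S, R, n_obs=8, subject_id="s0"):
    obs = []
    t = 0.0
    for _ in range(n_obs):
        obs.append(Observation(t, int(rng.integers(0, S)), rng.normal(0, 0.5, R)))
        t += rng.uniform(0.2, 1.0)
    return Trajectory(subject_id, obs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_model(rng):
    """Full 3-state transition-dependent model with 2 covariates."""
    struct = TransitionStructure.full(3)
    params = ParameterSet(
        struct,
        rng.uniform(0.2, 1.0, struct.n_transitions),
        rng.normal(0, 0.4, (struct.n_transitions, 2)),
        covariate_names=("age", "relapse"),
    )
    return params


@pytest.fixture
def toy_dataset(rng, toy_model):
    space = StateSpace.of_size(3)
    trajs = [
        random_trajectory(rng, 3, 2, n_obs=6, subject_id=f"s{m}") for m in range(8)
    ]
    return PanelDataset(trajs, space, covariate_names=("age", "relapse"))
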