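"""Interval-censored log-likelihood and its exact score."""

import numpy as np
import pytest

from ctmarkov.likelihood import (
    Observation,
    PanelDataset,
    Trajectory,
    dataset_loglik,
    dataset_score,
    interval_dQ,
    subject_loglik,
    subject_score,
)
from ctmarkov.model import ParameterSet, StateSpace, TransitionStructure

from conftest import random_trajectory


def one_way_two_state(rate=0.5):
    struct = TransitionStructure(2, [(0, 1)])
    return ParameterSet(struct, np.array([rate]), np.zeros((1, 0)), covariate_names=())


def finite_difference_score(params, dataset, scale, h=1e-6):
    theta = params.to_theta(scale)
    grad = np.zeros_like(theta)
    for i in range(theta.size):
        for sgn in (1, -1):
            t2 = theta.copy()
            t2[i] += sgn * h
            p2 = ParameterSet.from_theta(
                t2,
                params.structure,
                params.covariate_names,
                mode=params.mode,
                scale=scale,
            )
            grad[i] += sgn * dataset_loglik(p2, dataset) / (2 * h)
    return grad


class TestContainers:
    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            Trajectory("a", [Observation(0.0, 0), Observation(0.0, 1)])

    def test_unknown_state_rejected(self, rng):
        traj = Trajectory("a", [Observation(0.0, 7), Observation(1.0, 0)])
        with pytest.raises(KeyError):
            PanelDataset([traj], StateSpace.of_size(3))

    def test_covariate_schema_enforced(self):
        traj = Trajectory("a", [Observation(0.0, 0, [1.0]), Observation(1.0, 1, [1.0])])
        with pytest.raises(ValueError):
            PanelDataset([traj], StateSpace.of_size(2), covariate_names=("x", "y"))

    def test_interval_compilation_uses_start_covariates(self):
        traj = Trajectory(
            "a",
            [
                Observation(0.0, 0, [10.0]),
                Observation(1.0, 1, [20.0]),
                Observation(3.0, 0, [30.0]),
            ],
        )
        ds = PanelDataset([traj], StateSpace.of_size(2), covariate_names=("x",))
        ivs = ds.intervals
        assert np.allclose(ivs.tau, [1.0, 2.0])
        assert np.allclose(ivs.Z.ravel(), [10.0, 20.0])  # carry-forward


class TestIntervalDQ:
    def test_q0_direction_with_zero_betas(self):
        struct = TransitionStructure.full(3)
        params = ParameterSet(
            struct, np.full(6, 0.4), np.zeros((6, 1)), covariate_names=("x",)
        )
        tau = 1.7
        out = interval_dQ(params, tau, np.array([0.3]), which=0, scale="raw")
        i, j = struct.pairs[0]
        expected = np.zeros((3, 3))
        expected[i, j], expected[i, i] = tau, -tau
        assert np.allclose(out, expected)

    def test_beta_direction_vanishes_at_zero_covariate(self):
        struct = TransitionStructure.full(3)
        params = ParameterSet(
            struct, np.full(6, 0.4), np.full((6, 1), 0.5), covariate_names=("x",)
        )
        out = interval_dQ(params, 1.0, np.array([0.0]), which=1, scale="raw")
        assert np.allclose(out, 0.0)

    @pytest.mark.parametrize("scale", ["raw", "log_q0"])
    def test_matches_finite_differences(self, rng, toy_model, scale):
        from ctmarkov.model import build_intensity_matrix

        tau, z = 0.9, rng.normal(size=2)
        theta = toy_model.to_theta(scale)
        h = 1e-7
        for which in range(toy_model.n_params):
            fd = np.zeros((3, 3))
            for sgn in (1, -1):
                t2 = theta.copy()
                t2[which] += sgn * h
                p2 = ParameterSet.from_theta(
                    t2, toy_model.structure, toy_model.covariate_names, scale=scale
                )
                fd += sgn * build_intensity_matrix(p2, z) * tau / (2 * h)
            out = interval_dQ(toy_model, tau, z, which, scale=scale)
            assert np.abs(out - fd).max() < 1e-6


class TestLoglik:
    def test_two_state_stay_closed_form(self):
        params = one_way_two_state(0.5)
        traj = Trajectory("a", [Observation(0.0, 0), Observation(2.0, 0)])
        assert np.isclose(subject_loglik(params, traj), -1.0)  # log e^{-q tau}

    def test_absorbing_state_contributes_zero(self):
        params = one_way_two_state(0.5)
        traj = Trajectory(
            "a", [Observation(t, 1) for t in np.arange(0.0, 3.0, 0.5)]
        )
        assert subject_loglik(params, traj) == pytest.approx(0.0)

    def test_dataset_sum_of_subjects(self, rng, toy_model):
        space = StateSpace.of_size(3)
        trajs = [random_trajectory(rng, 3, 2, subject_id=f"s{m}") for m in range(4)]
        ds = PanelDataset(trajs, space, ("age", "relapse"))
        total = dataset_loglik(toy_model, ds)
        parts = sum(subject_loglik(toy_model, t, ds) for t in trajs)
        assert np.isclose(total, parts)

    def test_subject_permutation_invariance(self, rng, toy_model):
        space = StateSpace.of_size(3)
        trajs = [random_trajectory(rng, 3, 2, subject_id=f"s{m}") for m in range(5)]
        ds1 = PanelDataset(trajs, space, ("age", "relapse"))
        ds2 = PanelDataset(trajs[::-1], space, ("age", "relapse"))
        assert np.isclose(dataset_loglik(toy_model, ds1), dataset_loglik(toy_model, ds2))
        assert np.allclose(
            dataset_score(toy_model, ds1), dataset_score(toy_model, ds2)
        )

    def test_state_relabelling_invariance(self, rng):
        # permuting state labels and parameters consistently leaves the
        # likelihood unchanged
        perm = np.array([2, 0, 1])
        struct = TransitionStructure.full(3)
        q0 = rng.uniform(0.2, 1.0, 6)
        beta = rng.normal(0, 0.3, (6, 1))
        params = ParameterSet(struct, q0, beta, covariate_names=("x",))
        pairs_perm = [(perm[i], perm[j]) for i, j in struct.pairs]
        order = [struct.pairs.index((i, j)) for i, j in sorted(pairs_perm)]
        # build permuted parameter set aligned with the canonical pair order
        struct2 = TransitionStructure(3, sorted(pairs_perm))
        inv = [pairs_perm.index(p) for p in struct2.pairs]
        params2 = ParameterSet(struct2, q0[inv], beta[inv], covariate_names=("x",))
        traj = random_trajectory(rng, 3, 1, n_obs=7)
        relabelled = Trajectory(
            traj.subject_id,
            [Observation(o.time, int(perm[o.state]), o.z) for o in traj.observations],
        )
        assert np.isclose(
            subject_loglik(params, traj), subject_loglik(params2, relabelled)
        )

    def test_degenerate_interval_diagnosed(self):
        params = one_way_two_state(0.5)
        # a 1 -> 0 move is structurally impossible
        traj = Trajectory("a", [Observation(0.0, 1), Observation(1.0, 0)])
        space = StateSpace.of_size(2)
        ds = PanelDataset([traj], space)
        ll, diag = dataset_loglik(params, ds, return_diagnostics=True)
        assert diag["degenerate_intervals"] == 1
        assert ll < -600  # floored at log(1e-300)


class TestScore:
    def test_two_state_stay_raw_scale(self):
        # d/dq log e^{-q tau} = -tau
        params = one_way_two_state(0.8)
        traj = Trajectory("a", [Observation(0.0, 0), Observation(2.0, 0)])
        g = subject_score(params, traj, scale="raw")
        assert np.isclose(g[0], -2.0)

    def test_duplicated_trajectory_doubles_score(self, rng, toy_model):
        space = StateSpace.of_size(3)
        traj = random_trajectory(rng, 3, 2)
        ds1 = PanelDataset([traj], space, ("age", "relapse"))
        ds2 = PanelDataset(
            [traj, Trajectory("b", traj.observations)], space, ("age", "relapse")
        )
        assert np.allclose(
            dataset_score(toy_model, ds2), 2 * dataset_score(toy_model, ds1)
        )

    @pytest.mark.parametrize("scale", ["raw", "log_q0"])
    @pytest.mark.parametrize("mode", ["transition_dependent", "transition_independent"])
    def test_matches_finite_differences(self, rng, scale, mode):
        for S, R in ((2, 1), (3, 2), (4, 0)):
            struct = TransitionStructure.full(S)
            beta_shape = (struct.n_transitions, R) if mode == "transition_dependent" else (R,)
            params = ParameterSet(
                struct,
                rng.uniform(0.2, 1.0, struct.n_transitions),
                rng.normal(0, 0.3, beta_shape),
                mode=mode,
                covariate_names=tuple(f"z{r}" for r in range(R)),
            )
            space = StateSpace.of_size(S)
            trajs = [random_trajectory(rng, S, R, n_obs=6, subject_id=f"s{m}") for m in range(3)]
            ds = PanelDataset(trajs, space, tuple(f"z{r}" for r in range(R)))
            g = dataset_score(params, ds, scale=scale)
            fd = finite_difference_score(params, ds, scale)
            assert np.abs(g - fd).max() / max(np.abs(fd).max(), 1.0) < 1e-5

    def test_adjoint_equals_blockwise(self, rng, toy_model, toy_dataset):
        for scale in ("raw", "log_q0"):
            fast = dataset_score(toy_model, toy_dataset, scale=scale)
            ref = dataset_score(toy_model, toy_dataset, scale=scale, method="blockwise")
            assert np.abs(fast - ref).max() < 1e-12

    def test_raw_log_chain_rule(self, toy_model, toy_dataset):
        # d/d(log q0) = q0 * d/dq0, betas untouched
        g_raw = dataset_score(toy_model, toy_dataset, scale="raw")
        g_log = dataset_score(toy_model, toy_dataset, scale="log_q0")
        R = toy_model.R
        block_raw = g_raw.reshape(-1, 1 + R)
        block_log = g_log.reshape(-1, 1 + R)
        assert np.allclose(block_log[:, 0], block_raw[:, 0] * toy_model.q0)
        assert np.allclose(block_log[:, 1:], block_raw[:, 1:])

    def test_score_vanishes_at_fitted_maximum(self, rng):
        # fit a tiny model to its own simulated data with a tight
        # quasi-Newton tolerance; the analytic score must be flat there
        from scipy.optimize import minimize

        from ctmarkov.simulator import SimConfig, simulate_dataset

        struct = TransitionStructure.full(2)
        true = ParameterSet(
            struct, np.array([0.4, 0.6]), np.zeros((2, 1)), covariate_names=("x",)
        )
        ds = simulate_dataset(
            SimConfig(M=40, params=true, t_max=6.0, dummy_interval=0.5, seed=21)
        )

        def negll(th):
            p = ParameterSet.from_theta(th, struct, ds.covariate_names)
            return -dataset_loglik(p, ds)

        def neggrad(th):
            p = ParameterSet.from_theta(th, struct, ds.covariate_names)
            return -dataset_score(p, ds)

        res = minimize(
            negll, true.to_theta("log_q0"), jac=neggrad, method="L-BFGS-B",
            options={"gtol": 1e-7, "ftol": 0.0},
        )
        g = dataset_score(
            ParameterSet.from_theta(res.x, struct, ds.covariate_names), ds
        )
        assert np.abs(g).max() < 1e-4

    def test_impossible_transition_flags_nonfinite(self):
        params = one_way_two_state(0.5)
        traj = Trajectory("a", [Observation(0.0, 1), Observation(1.0, 0)])
        g = subject_score(params, traj)
        assert not np.all(np.isfinite(g))
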