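"""Hessian constructions, Wald intervals, hazard ratios."""

import numpy as np
import pandas as pd
import pytest

from ctmarkov.inference import (
    HessianResult,
    hessian_pade,
    hessian_power_series,
    interval_d2Q,
    wald_report,
)
from ctmarkov.likelihood import (
    Observation,
    PanelDataset,
    Trajectory,
    dataset_score,
)
from ctmarkov.model import ParameterSet, StateSpace, TransitionStructure

from conftest import random_trajectory


def fd_hessian(params, dataset, scale, h=1e-5):
    theta = params.to_theta(scale)
    p = theta.size
    H = np.zeros((p, p))
    for i in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        gp = dataset_score(
            ParameterSet.from_theta(tp, params.structure, params.covariate_names,
                                    mode=params.mode, scale=scale),
            dataset, scale=scale)
        gm = dataset_score(
            ParameterSet.from_theta(tm, params.structure, params.covariate_names,
                                    mode=params.mode, scale=scale),
            dataset, scale=scale)
        H[:, i] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


@pytest.fixture
def small_panel(rng, toy_model):
    space = StateSpace.of_size(3)
    trajs = [random_trajectory(rng, 3, 2, n_obs=6, subject_id=f"s{m}") for m in range(6)]
    return PanelDataset(trajs, space, ("age", "relapse"))


@pytest.fixture(scope="module")
def fitted_small():
    """A small simulated 2-state model fitted to its own data."""
    from ctmarkov.optimizer import FitConfig, fit, suggested_lr_scale
    from ctmarkov.simulator import SimConfig, simulate_dataset

    struct = TransitionStructure.full(2)
    true = ParameterSet(
        struct, np.array([0.4, 0.5]), np.array([[0.3], [-0.2]]), covariate_names=("x",)
    )
    ds = simulate_dataset(
        SimConfig(M=80, params=true, t_max=8, dummy_interval=0.5, seed=31)
    )
    cfg = FitConfig(
        batch_size=ds.M,
        lr_scale=100 * suggested_lr_scale(ds),
        max_iters=250,
        restarts=1,
        seed=31,
        trace_loglik_every=0,
    )
    return fit(ds, cfg, structure=struct), ds


class TestIntervalD2Q:
    @pytest.mark.parametrize("scale", ["raw", "log_q0"])
    def test_matches_finite_differences_of_dQ(self, rng, toy_model, scale):
        from ctmarkov.likelihood import interval_dQ

        tau, z = 0.8, rng.normal(size=2)
        theta = toy_model.to_theta(scale)
        h = 1e-6
        n_par = toy_model.n_params
        for l1 in range(0, n_par, 5):
            for l2 in range(0, n_par, 7):
                fd = np.zeros((3, 3))
                for sgn in (1, -1):
                    t2 = theta.copy()
                    t2[l2] += sgn * h
                    p2 = ParameterSet.from_theta(
                        t2, toy_model.structure, toy_model.covariate_names, scale=scale
                    )
                    fd += sgn * interval_dQ(p2, tau, z, l1, scale=scale) / (2 * h)
                out = interval_d2Q(toy_model, tau, z, l1, l2, scale=scale)
                assert np.abs(out - fd).max() < 1e-6


class TestHessianPade:
    def test_two_state_closed_form(self):
        # data: n00 stay-intervals and n01 jump-intervals of length tau;
        # loglik(q) = -n00 q tau + n01 log(1 - e^{-q tau}) on the raw scale
        q, tau, n00, n01 = 0.6, 0.8, 7, 3
        struct = TransitionStructure(2, [(0, 1)])
        params = ParameterSet(struct, np.array([q]), np.zeros((1, 0)), covariate_names=())
        obs = [Observation(0.0, 0)]
        t = 0.0
        for _ in range(n00):
            t += tau
            obs.append(Observation(t, 0))
        trajs = [Trajectory("stay", obs)]
        for k in range(n01):
            trajs.append(
                Trajectory(f"jump{k}", [Observation(0.0, 0), Observation(tau, 1)])
            )
        ds = PanelDataset(trajs, StateSpace.of_size(2), ())
        H = hessian_pade(params, ds, scale="raw").H
        e = np.exp(-q * tau)
        expected = -n01 * tau**2 * e / (1 - e) ** 2
        assert H.shape == (1, 1)
        assert H[0, 0] == pytest.approx(expected, rel=1e-8)

    @pytest.mark.parametrize("scale", ["raw", "log_q0"])
    def test_matches_finite_differences(self, toy_model, small_panel, scale):
        H = hessian_pade(toy_model, small_panel, scale=scale).H
        Hfd = fd_hessian(toy_model, small_panel, scale)
        assert np.abs(H - Hfd).max() / np.abs(Hfd).max() < 1e-3

    def test_fast_equals_pairwise(self, toy_model, small_panel):
        Hf = hessian_pade(toy_model, small_panel, scale="log_q0").H
        Hp = hessian_pade(toy_model, small_panel, scale="log_q0", method="pairwise").H
        assert np.abs(Hf - Hp).max() < 1e-10

    def test_transition_independent_mode(self, rng, small_panel):
        struct = TransitionStructure.full(3)
        params = ParameterSet(
            struct,
            rng.uniform(0.3, 0.9, 6),
            rng.normal(0, 0.3, 2),
            mode="transition_independent",
            covariate_names=("age", "relapse"),
        )
        H = hessian_pade(params, small_panel, scale="log_q0").H
        Hfd = fd_hessian(params, small_panel, "log_q0")
        assert np.abs(H - Hfd).max() / np.abs(Hfd).max() < 1e-3

    def test_symmetric(self, toy_model, small_panel):
        H = hessian_pade(toy_model, small_panel).H
        assert np.abs(H - H.T).max() <= 1e-6 * max(np.abs(H).max(), 1.0)


class TestHessianPowerSeries:
    def test_scalar_chain_symbolic(self):
        # stay entry 1 - q tau + (q tau)^2/2; second log-derivative wrt q:
        # d2/dq2 log b = (b * b'' - b'^2) / b^2 with b' = -tau + q tau^2, b'' = tau^2
        q, tau, n00 = 0.4, 0.5, 5
        struct = TransitionStructure(2, [(0, 1)])
        params = ParameterSet(struct, np.array([q]), np.zeros((1, 0)), covariate_names=())
        obs = [Observation(0.0, 0)]
        t = 0.0
        for _ in range(n00):
            t += tau
            obs.append(Observation(t, 0))
        ds = PanelDataset([Trajectory("a", obs)], StateSpace.of_size(2), ())
        H = hessian_power_series(params, ds, scale="raw").H
        b = 1 - q * tau + 0.5 * (q * tau) ** 2
        bp = -tau + q * tau**2
        bpp = tau**2
        expected = n00 * (b * bpp - bp**2) / b**2
        assert H[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_converges_to_pade_as_tau_shrinks(self, rng):
        # the truncation error is O(||Q tau||^3): halving tau should shrink
        # the Hessian discrepancy by roughly 2^3
        struct = TransitionStructure.full(2)
        params = ParameterSet(
            struct, np.array([0.5, 0.7]), np.zeros((2, 0)), covariate_names=()
        )

        def discrepancy(tau):
            obs = [Observation(k * tau, k % 2) for k in range(6)]
            ds = PanelDataset([Trajectory("a", obs)], StateSpace.of_size(2), ())
            Hp = hessian_pade(params, ds, scale="log_q0").H
            Hs = hessian_power_series(params, ds, scale="log_q0").H
            return np.abs(Hp - Hs).max()

        d1, d2 = discrepancy(0.2), discrepancy(0.1)
        assert d1 / d2 == pytest.approx(8.0, rel=0.5)

    def test_se_agreement_at_short_intervals(self, fitted_small):
        # at ||Q tau|| ~ 0.2 the truncated-series and exact observed
        # information give close (not identical) standard errors
        res, ds = fitted_small
        se_pade = wald_report(
            hessian_pade(res.params, ds), res.params
        ).table.se_fit_scale.to_numpy()
        se_power = wald_report(
            hessian_power_series(res.params, ds), res.params
        ).table.se_fit_scale.to_numpy()
        assert np.abs(se_power / se_pade - 1).max() < 0.25


class TestWaldReport:
    def _unit_result(self, params):
        H = -np.eye(params.n_params)
        return HessianResult(H=H, method="pade", scale="log_q0")

    def test_unit_information_interval(self):
        struct = TransitionStructure(2, [(0, 1)])
        params = ParameterSet(
            struct, np.array([1.0]), np.zeros((1, 1)), covariate_names=("x",)
        )
        rep = wald_report(self._unit_result(params), params)
        beta_row = rep.table[rep.table.kind == "beta"].iloc[0]
        # estimate 0, SE 1: CI is +/- 1.96, no rejection
        assert beta_row.estimate == 0.0
        assert beta_row.se == pytest.approx(1.0)
        assert beta_row.lo == pytest.approx(-1.959964, abs=1e-5)
        assert beta_row.hi == pytest.approx(1.959964, abs=1e-5)
        assert not beta_row.reject

    def test_zero_beta_gives_unit_hazard_ratio(self):
        struct = TransitionStructure(2, [(0, 1)])
        params = ParameterSet(
            struct, np.array([1.0]), np.zeros((1, 1)), covariate_names=("x",)
        )
        rep = wald_report(self._unit_result(params), params)
        hr = rep.hazard_ratios.iloc[0]
        assert hr.hr == pytest.approx(1.0)
        assert hr.lo < 1.0 < hr.hi

    def test_duplicating_data_shrinks_se_by_sqrt2(self, fitted_small):
        res, ds = fitted_small
        doubled = PanelDataset(
            ds.trajectories
            + [
                Trajectory(f"copy{m}", t.observations)
                for m, t in enumerate(ds.trajectories)
            ],
            ds.state_space,
            ds.covariate_names,
        )
        se1 = wald_report(
            hessian_pade(res.params, ds), res.params
        ).table.se_fit_scale.to_numpy()
        se2 = wald_report(
            hessian_pade(res.params, doubled), res.params
        ).table.se_fit_scale.to_numpy()
        ratio = se1 / se2
        assert np.abs(ratio - np.sqrt(2)).max() < 0.05 * np.sqrt(2)

    def test_q0_interval_positive_and_delta_se(self, fitted_small):
        res, ds = fitted_small
        rep = wald_report(hessian_pade(res.params, ds), res.params)
        q_rows = rep.table[rep.table.kind == "q0"]
        assert (q_rows.lo > 0).all()
        assert np.allclose(q_rows.se, q_rows.estimate * q_rows.se_fit_scale)
        assert (q_rows.lo <= q_rows.estimate).all()
        assert (q_rows.estimate <= q_rows.hi).all()

    def test_singular_information_warns(self):
        struct = TransitionStructure(2, [(0, 1)])
        params = ParameterSet(struct, np.array([1.0]), np.zeros((1, 0)), covariate_names=())
        H = HessianResult(H=np.zeros((1, 1)), method="pade", scale="log_q0")
        with pytest.warns(UserWarning, match="singular|pseudo"):
            wald_report(H, params)
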