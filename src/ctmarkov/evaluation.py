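"""Monte-Carlo operating characteristics and descriptive panel summaries.

The harness answers the standard frequentist questions about the whole
pipeline (simulate -> fit -> confidence intervals): per-parameter bias and
sampling variance of the estimates, empirical coverage of the nominal 95%
intervals, and the rejection rate of the Wald test of "parameter = 0" —
type-I error under a null scenario, power under an alternative.

Descriptive helpers: the normalized empirical transition matrix built from
adjacent visits, the relative-frequency filter that drops rarely observed
transitions from the model, and the EDSS state-collapsing rule used to map
the raw 0-10 half-point disability scale onto 9 working states.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import hessian_pade, hessian_power_series, wald_report
from .likelihood import PanelDataset
from .model import (
    TRANSITION_DEPENDENT,
    ParameterSet,
    TransitionStructure,
)
from .optimizer import FitConfig, fit, suggested_lr_scale
from .simulator import SimConfig, simulate_dataset

__all__ = [
    "ScenarioSpec",
    "MonteCarloReport",
    "run_scenario",
    "empirical_transition_matrix",
    "transition_frequency_filter",
    "collapse_states",
]


@dataclass
class ScenarioSpec:
    """One simulation scenario for the Monte-Carlo harness.

    The truth is a band generator: transitions with ``|i - j| <= band``
    carry baseline intensity ``q0_adjacent / |i - j|`` (one-step moves are
    the fastest), and every modelled beta equals ``true_beta`` (0 gives the
    null scenario).  Covariates are uniform, centered at zero, redrawn at
    every visit.
    """

    M: int = 500
    S: int = 8
    R: int = 10
    true_beta: float = 0.0
    q0_adjacent: float = 0.5
    band: int = 1
    n_replicates: int = 100
    restarts: int = 20
    ci_method: str = "pade"
    mode: str = TRANSITION_DEPENDENT
    t_max: float = 15.0
    dummy_interval: float = 0.5
    batch_size: int = 50
    max_iters: int = 300
    lr_scale: float | None = None  # None: suggested_lr_scale per dataset
    seed: int | None = None

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.ci_method not in ("pade", "power"):
            raise ValueError("ci_method must be 'pade' or 'power'")

    def true_parameters(self) -> ParameterSet:
        structure = TransitionStructure.adjacent(self.S, width=self.band)
        q0 = np.array(
            [self.q0_adjacent / abs(i - j) for i, j in structure.pairs]
        )
        names = tuple(f"z{r + 1}" for r in range(self.R))
        if self.mode == TRANSITION_DEPENDENT:
            beta = np.full((structure.n_transitions, self.R), float(self.true_beta))
        else:
            beta = np.full(self.R, float(self.true_beta))
        return ParameterSet(structure, q0, beta, mode=self.mode, covariate_names=names)


@dataclass
class MonteCarloReport:
    """Operating characteristics aggregated over replicates.

    ``per_parameter`` has one row per model parameter with columns
    ``bias`` (mean of estimate minus truth), ``variance`` (across
    replicates), ``coverage`` and ``rejection``.  ``aggregate`` averages
    within parameter classes (baseline intensities vs betas), using the
    mean of |bias| so opposite signs cannot cancel.
    """

    per_parameter: pd.DataFrame
    aggregate: pd.DataFrame
    n_replicates: int
    n_failed: int
    realized_n_obs: float
    estimates: np.ndarray = field(repr=False, default=None)

    def summary(self, kind: str) -> dict:
        row = self.aggregate.loc[self.aggregate["kind"] == kind]
        return {} if row.empty else row.iloc[0].to_dict()


def run_scenario(spec: ScenarioSpec) -> MonteCarloReport:
    """Simulate, fit, and score ``n_replicates`` datasets against the truth."""
    true = spec.true_parameters()
    theta_true = true.to_theta("raw")
    labels = true.theta_labels()
    kinds = ["q0" if lab.startswith("q0") else "beta" for lab in labels]
    n_par = len(theta_true)

    root = np.random.SeedSequence(spec.seed)
    rep_seeds = root.spawn(spec.n_replicates)

    ests = np.full((spec.n_replicates, n_par), np.nan)
    covered = np.full((spec.n_replicates, n_par), np.nan)
    rejected = np.full((spec.n_replicates, n_par), np.nan)
    n_obs = []
    n_failed = 0

    for rep, seed_seq in enumerate(rep_seeds):
        child = np.random.default_rng(seed_seq)
        sim_seed, fit_seed = child.integers(2**31 - 1, size=2)
        try:
            dataset = simulate_dataset(
                SimConfig(
                    M=spec.M,
                    params=true,
                    t_max=spec.t_max,
                    dummy_interval=spec.dummy_interval,
                    seed=int(sim_seed),
                )
            )
            n_obs.append(dataset.n_intervals + dataset.M)
            lr = spec.lr_scale or 100.0 * suggested_lr_scale(dataset)
            cfg = FitConfig(
                batch_size=spec.batch_size,
                lr_scale=lr,
                max_iters=spec.max_iters,
                restarts=spec.restarts,
                seed=int(fit_seed),
                trace_loglik_every=0,
            )
            result = fit(dataset, cfg, structure=true.structure, mode=spec.mode)
            if spec.ci_method == "pade":
                hess = hessian_pade(result.params, dataset, scale=result.scale)
            else:
                hess = hessian_power_series(result.params, dataset, scale=result.scale)
            report = wald_report(hess, result.params)
        except Exception as exc:  # noqa: BLE001 - failed fits are counted
            warnings.warn(f"replicate {rep} failed: {exc}", stacklevel=2)
            n_failed += 1
            continue

        tab = report.table
        est_nat = tab["estimate"].to_numpy()
        ests[rep] = est_nat
        is_q0 = np.array([k == "q0" for k in kinds])
        # coverage on the estimation scale: log for q0 (equivalent to the
        # exponentiated interval containing the true rate), natural for beta
        lo_f = tab["lo_fit_scale"].to_numpy()
        hi_f = tab["hi_fit_scale"].to_numpy()
        truth_fit = np.where(
            is_q0, np.log(np.where(is_q0, theta_true, 1.0)), theta_true
        )
        covered[rep] = (lo_f <= truth_fit) & (truth_fit <= hi_f)
        rejected[rep] = tab["reject"].to_numpy()

    ok = ~np.isnan(ests[:, 0])
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise RuntimeError("every replicate failed")
    bias = np.nanmean(ests[ok] - theta_true, axis=0)
    variance = (
        np.nanvar(ests[ok], axis=0, ddof=1) if n_ok > 1 else np.zeros(n_par)
    )
    coverage = np.nanmean(covered[ok], axis=0)
    rejection = np.nanmean(rejected[ok], axis=0)

    per_parameter = pd.DataFrame(
        dict(
            parameter=labels,
            kind=kinds,
            true=theta_true,
            bias=bias,
            variance=variance,
            coverage=coverage,
            rejection=rejection,
        )
    )
    aggregate = (
        per_parameter.assign(abs_bias=lambda d: d.bias.abs())
        .groupby("kind", as_index=False)
        .agg(
            bias=("abs_bias", "mean"),
            variance=("variance", "mean"),
            coverage=("coverage", "mean"),
            rejection=("rejection", "mean"),
        )
    )
    return MonteCarloReport(
        per_parameter=per_parameter,
        aggregate=aggregate,
        n_replicates=n_ok,
        n_failed=n_failed,
        realized_n_obs=float(np.mean(n_obs)) if n_obs else np.nan,
        estimates=ests[ok],
    )


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

def transition_counts(dataset: PanelDataset) -> np.ndarray:
    """Counts of adjacent-visit ``(from, to)`` pairs, internal indexing."""
    S = dataset.state_space.S
    ivs = dataset.intervals
    counts = np.zeros((S, S))
    np.add.at(counts, (ivs.frm, ivs.to), 1.0)
    return counts


def empirical_transition_matrix(dataset: PanelDataset) -> np.ndarray:
    """Row-normalized counts of adjacent clinical assessments.

    Rows with no observations are returned as all zeros (with a warning)
    rather than NaN.
    """
    counts = transition_counts(dataset)
    totals = counts.sum(axis=1, keepdims=True)
    empty = np.flatnonzero(totals.ravel() == 0)
    if empty.size:
        warnings.warn(
            f"states {empty.tolist()} never occupied at an interval start; "
            "their rows are all zero",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), 0.0)
    return P


def transition_frequency_filter(
    dataset: PanelDataset, threshold: float = 0.01
) -> TransitionStructure:
    """Keep ordered pairs carrying at least ``threshold`` of transition data.

    The denominator is the total count of observed off-diagonal adjacent
    transitions; the boundary is inclusive (exactly 1% is kept).
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    counts = transition_counts(dataset)
    np.fill_diagonal(counts, 0.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("dataset contains no observed state changes")
    keep = [
        (i, j)
        for i in range(counts.shape[0])
        for j in range(counts.shape[1])
        if i != j and counts[i, j] > 0 and counts[i, j] / total >= threshold
    ]
    if not keep:
        raise ValueError(
            f"no transition reaches the {threshold:.0%} frequency threshold"
        )
    return TransitionStructure(dataset.state_space.S, keep)


def collapse_states(raw):
    """Collapse a raw EDSS value (0-10, half points) to a working state 0-8.

    0 stays 0, values below 8 are rounded down to their integer part, and
    everything at or above 8 becomes 8.
    """
    arr = np.asarray(raw, dtype=float)
    if np.any(arr < 0) or np.any(arr > 10):
        raise ValueError("EDSS values must lie in [0, 10]")
    out = np.minimum(np.floor(arr), 8).astype(int)
    return out if out.ndim else int(out)
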