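"""Readers and writers for panel CSVs, fit artifacts, and configs.

The on-disk panel format is long: one row per (subject, visit), with
mandatory columns ``subject_id``, ``time``, ``state`` and any number of
numeric covariate columns.  Comma-separated, UTF-8, header mandatory,
``.`` decimal.  Times are in whatever unit the file uses (years
recommended); all rates are "per time unit of the input".

Fit artifacts are flat JSON documents carrying the estimate on both
scales, the winning restart's provenance, the covariate centering offsets
(so hazard ratios at the mean covariate value remain computable), and a
hash of the fitting configuration for reload-time consistency checks.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .likelihood import Observation, PanelDataset, Trajectory
from .model import ParameterSet, StateSpace, TransitionStructure
from .optimizer import FitConfig, FitResult

__all__ = [
    "read_panel",
    "write_panel",
    "write_fit",
    "read_fit",
    "config_hash",
]

_REQUIRED = ("subject_id", "time", "state")


def read_panel(
    path,
    covariates: list[str] | None = None,
    state_space: StateSpace | None = None,
    center: bool = True,
    collapse_edss: bool = False,
) -> PanelDataset:
    """Load a long-format panel CSV into a :class:`PanelDataset`.

    ``covariates`` defaults to every numeric column other than the
    required three.  With ``center=True`` covariates are shifted to mean
    zero and the offsets stored on the dataset.  ``collapse_edss`` applies
    the EDSS 0-8 state-collapsing rule to the ``state`` column first.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"panel file lacks required columns {missing}")
    if df[list(_REQUIRED)].isna().any().any():
        raise ValueError("subject_id/time/state must be complete (no missing values)")
    if collapse_edss:
        from .evaluation import collapse_states

        df["state"] = collapse_states(df["state"].to_numpy())
    dup = df.duplicated(subset=["subject_id", "time"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["subject_id", "time"]].drop_duplicates()
        raise ValueError(
            f"duplicate (subject, time) rows:\n{offenders.to_string(index=False)}"
        )
    if covariates is None:
        covariates = [
            c
            for c in df.columns
            if c not in _REQUIRED and pd.api.types.is_numeric_dtype(df[c])
        ]
    if df[covariates].isna().any().any():
        raise ValueError("covariates must be complete; no imputation is performed")

    df = df.sort_values(["subject_id", "time"], kind="stable")
    offsets = np.zeros(len(covariates))
    if center and covariates:
        offsets = df[covariates].mean().to_numpy()
        df = df.copy()
        df[covariates] = df[covariates] - offsets

    if state_space is None:
        state_space = StateSpace(sorted(df["state"].unique()))
    trajectories = []
    for sid, grp in df.groupby("subject_id", sort=True):
        obs = [
            Observation(row.time, row.state, row[covariates].to_numpy(dtype=float))
            for _, row in grp.iterrows()
        ]
        trajectories.append(Trajectory(sid, obs))
    return PanelDataset(
        trajectories, state_space, covariate_names=tuple(covariates), centering=offsets
    )


def write_panel(dataset: PanelDataset, path) -> None:
    """Write a dataset back to the canonical long CSV (un-centering applied)."""
    rows = []
    for traj in dataset.trajectories:
        for obs in traj.observations:
            row = {"subject_id": traj.subject_id, "time": obs.time, "state": obs.state}
            for name, val, off in zip(
                dataset.covariate_names, obs.z, dataset.centering
            ):
                row[name] = val + off
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping or dataclass."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = {k: getattr(obj, k) for k in obj.__dataclass_fields__}
    payload = json.dumps(obj, sort_keys=True, default=repr).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_fit(result: FitResult, path, config: FitConfig | None = None, extra: dict | None = None) -> None:
    """Serialize a fit result (lossless for theta on both scales)."""
    params = result.params
    doc = {
        "structure": {"S": params.structure.S, "pairs": list(params.structure.pairs)},
        "mode": params.mode,
        "covariate_names": list(params.covariate_names),
        "q0": params.q0.tolist(),
        "beta": params.beta.tolist(),
        "theta_hat": result.theta_hat.tolist(),
        "scale": result.scale,
        "loglik": result.loglik,
        "converged": bool(result.converged),
        "n_iters": int(result.n_iters),
        "restart_index": int(result.restart_index),
        "config_hash": config_hash(config) if config is not None else None,
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2))


def read_fit(path, config: FitConfig | None = None) -> FitResult:
    """Reload a fit artifact; warns when the stored config hash differs."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"fit artifact not found: {p}")
    doc = json.loads(p.read_text())
    if config is not None and doc.get("config_hash") not in (None, config_hash(config)):
        warnings.warn(
            "fit artifact was produced under a different configuration",
            stacklevel=2,
        )
    structure = TransitionStructure(
        doc["structure"]["S"], [tuple(p) for p in doc["structure"]["pairs"]]
    )
    params = ParameterSet(
        structure,
        np.array(doc["q0"]),
        np.array(doc["beta"]),
        mode=doc["mode"],
        covariate_names=tuple(doc["covariate_names"]),
    )
    return FitResult(
        params=params,
        theta_hat=np.array(doc["theta_hat"]),
        scale=doc["scale"],
        loglik=doc["loglik"],
        converged=doc["converged"],
        n_iters=doc["n_iters"],
        restart_index=doc["restart_index"],
    )
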