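"""Observed-information standard errors, Wald tests, and hazard ratios.

Two Hessian constructions are offered for the panel log-likelihood:

``pade``
    Exact second derivatives.  Differentiating the block-matrix
    representation of the first derivative of ``Exp`` once more gives the
    second directional derivative as a corner block of the exponential of a
    ``4S x 4S`` block matrix (:func:`ctmarkov._expm.second_frechet_expm`).
    Per interval the quotient rule combines the observed entries of the
    zeroth, first and second derivatives of ``Exp(Q tau)``.

``power_series``
    The matrix exponential in the likelihood is replaced by its power
    series truncated after the quadratic term,
    ``I + Q tau + (Q tau)^2 / 2``, and the truncated log-likelihood is
    differentiated twice analytically.  Much cheaper for large state
    spaces, at the price of slightly *under*-estimating the variance
    (dropped series terms), hence slightly narrower intervals.

The default assembly route for ``pade`` exploits two structural facts to
stay affordable: every parameter direction is a scalar multiple of one of
the ``T`` per-transition base matrices ``D_t`` (``+1`` at ``(i,j)``, ``-1``
at ``(i,i)``), and the observed ``(s, s')`` entry of an ordered second-order
integral in directions ``(E1, E2)`` is, for fixed ``E1``, a linear
functional of ``E2`` that one extra block exponential evaluates for *all*
``E2`` at once.  The cost per interval is therefore ``T`` block
exponentials instead of one per parameter pair; the direct pair-by-pair
construction is retained (``method="pairwise"``) and agrees to rounding.

Standard errors are computed on the scale used for fitting (log baseline
intensities by default) and transformed back to natural scale by the delta
method; baseline-intensity confidence limits are exponentiated log-scale
limits, so they stay positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._expm import ordered_double_frechet, second_frechet_expm
from .likelihood import (
    PROB_FLOOR,
    PanelDataset,
    _Intervals,
    _score_arrays,
    interval_dQ,
)
from ._expm import expm, frechet_derivative_expm
from .model import (
    TRANSITION_DEPENDENT,
    TRANSITION_INDEPENDENT,
    ParameterSet,
    assemble_generators,
    intensities,
)

__all__ = [
    "HessianResult",
    "CIReport",
    "second_frechet_expm",
    "interval_d2Q",
    "hessian_pade",
    "hessian_power_series",
    "wald_report",
]

_CHUNK = 2048


@dataclass
class HessianResult:
    """Hessian of the log-likelihood at the estimate, plus diagnostics."""

    H: np.ndarray
    method: str
    scale: str
    n_excluded: int = 0
    negative_definite: bool | None = None

    def __post_init__(self):
        if self.negative_definite is None:
            try:
                np.linalg.cholesky(-self.H)
                self.negative_definite = True
            except np.linalg.LinAlgError:
                self.negative_definite = False


@dataclass
class CIReport:
    """Per-parameter Wald summary and transition-specific hazard ratios."""

    table: pd.DataFrame
    hazard_ratios: pd.DataFrame
    level: float
    method: str


# ---------------------------------------------------------------------------
# second derivative of Q*tau w.r.t. a parameter pair (reference route)
# ---------------------------------------------------------------------------

def interval_d2Q(
    params: ParameterSet,
    tau: float,
    z: np.ndarray,
    which1: int,
    which2: int,
    scale: str = "raw",
) -> np.ndarray:
    """Cross-curvature ``d^2 (Q(z) tau) / d theta_1 d theta_2``.

    Each intensity is log-linear in the parameters, ``q_ij = exp(log q0_ij
    + z . beta_ij)``, so on the log scale the second derivative of an entry
    is the entry times the product of the two first-order weights; on the
    raw scale the ``(q0, q0)`` curvature vanishes (the entry is linear in
    ``q0``) while mixed and beta-beta curvatures keep the same product
    form.  Parameters attached to different transitions never interact.
    """
    z = np.asarray(z, dtype=float).reshape(-1)
    S = params.structure.S
    q = intensities(params, z[None, :])[0]
    out = np.zeros((S, S))
    w1 = _direction_weights(params, z, which1)
    w2 = _direction_weights(params, z, which2)
    for t in range(params.structure.n_transitions):
        if w1[t] == 0.0 or w2[t] == 0.0:
            continue
        val = q[t] * tau * w1[t] * w2[t]
        if scale == "raw":
            q0_1 = _is_q0_param(params, which1, t)
            q0_2 = _is_q0_param(params, which2, t)
            if q0_1 and q0_2:
                val = 0.0  # the entry is linear in q0
            elif q0_1 or q0_2:
                val /= params.q0[t]
        i, j = params.structure.pairs[t]
        out[i, j] += val
        out[i, i] -= val
    return out


def _is_q0_param(params: ParameterSet, which: int, t: int) -> bool:
    if params.mode == TRANSITION_DEPENDENT:
        tt, k = divmod(which, 1 + params.R)
        return tt == t and k == 0
    return which == t


def _direction_weights(params: ParameterSet, z: np.ndarray, which: int) -> np.ndarray:
    """Per-transition weight ``w_t`` with ``dA/dtheta = sum_t q_t tau w_t D_t``.

    Log scale for ``q0`` entries yields weight 1; raw scale ``1/q0``; betas
    give ``z_r`` on their transition(s).  Used by the pairwise reference
    route; the fast route constructs the same weights in batch.
    """
    T = params.structure.n_transitions
    w = np.zeros(T)
    if params.mode == TRANSITION_DEPENDENT:
        t, k = divmod(which, 1 + params.R)
        w[t] = 1.0 if k == 0 else z[k - 1]
    else:
        if which < T:
            w[which] = 1.0
        else:
            w[:] = z[which - T]
    return w


# ---------------------------------------------------------------------------
# weight bookkeeping for the fast assembly
# ---------------------------------------------------------------------------

def _weight_tensor(params: ParameterSet, Z: np.ndarray) -> np.ndarray:
    """``w[n, t, k]``: weight of base direction ``D_t`` in slot ``k``.

    Slot 0 is the baseline-intensity parameter of transition ``t`` (on the
    log scale), slots ``1..R`` its betas.  The transition-independent model
    is the projection of this layout (shared betas sum over transitions).
    """
    n = Z.shape[0]
    T = params.structure.n_transitions
    R = params.R
    w = np.empty((n, T, 1 + R))
    w[..., 0] = 1.0
    if R:
        w[..., 1:] = Z[:, None, :]
    return w


def _projection(params: ParameterSet) -> np.ndarray | None:
    """Map from dependent-layout ``(t, k)`` to the model's flat theta."""
    if params.mode == TRANSITION_DEPENDENT:
        return None
    T = params.structure.n_transitions
    R = params.R
    L = np.zeros((T * (1 + R), T + R))
    for t in range(T):
        L[t * (1 + R), t] = 1.0
        for r in range(R):
            L[t * (1 + R) + 1 + r, T + r] = 1.0
    return L


def _raw_scale_correction(params: ParameterSet, qtau: np.ndarray, w: np.ndarray, scale: str):
    """Adjust slot-0 weights for the raw-q0 scale (chain rule 1/q0)."""
    if scale == "raw":
        w = w.copy()
        w[..., 0] = 1.0 / params.q0
    return w


# ---------------------------------------------------------------------------
# Padé Hessian
# ---------------------------------------------------------------------------

def hessian_pade(
    params: ParameterSet,
    dataset: PanelDataset,
    scale: str = "log_q0",
    method: str = "fast",
) -> HessianResult:
    """Hessian of the log-likelihood via block-matrix second derivatives."""
    if method == "pairwise":
        H, n_exc = _hessian_pairwise(params, dataset, scale)
    elif method == "fast":
        H, n_exc = _hessian_fast(params, dataset, scale)
    else:
        raise ValueError(f"unknown method {method!r}")
    H = (H + H.T) / 2.0
    return HessianResult(H=H, method="pade", scale=scale, n_excluded=n_exc)


def _hessian_fast(params: ParameterSet, dataset: PanelDataset, scale: str):
    ivs = dataset.intervals
    T = params.structure.n_transitions
    R = params.R
    rows, cols = params.structure.rows, params.structure.cols
    p_dep = T * (1 + R)
    H = np.zeros((p_dep, p_dep))
    n_excluded = 0
    S = params.structure.S

    for lo in range(0, ivs.tau.size, _CHUNK):
        sl = slice(lo, min(lo + _CHUNK, ivs.tau.size))
        sub = _Intervals(ivs.tau[sl], ivs.frm[sl], ivs.to[sl], ivs.Z[sl], ivs.subject[sl])
        p, gdot, q = _score_arrays(params, sub, scale)
        ok = p >= PROB_FLOOR
        n_excluded += int((~ok).sum())
        if not ok.all():
            sub = _Intervals(sub.tau[ok], sub.frm[ok], sub.to[ok], sub.Z[ok], sub.subject[ok])
            p, gdot, q = p[ok], gdot[ok], q[ok]
        n = p.size
        if n == 0:
            continue
        A = assemble_generators(params.structure, q) * sub.tau[:, None, None]
        qtau = q * sub.tau[:, None]
        gq = gdot / p[:, None]  # (n, T)

        # ordered second-order integrals: for each base direction t1, one
        # 3S-block exponential yields ord(D_t1, E)_{from,to} for all E
        Rmat = np.zeros((n, S, S))
        Rmat[np.arange(n), sub.to, sub.frm] = 1.0
        ordm = np.empty((n, T, T))
        for t1 in range(T):
            D = np.zeros((S, S))
            i, j = rows[t1], cols[t1]
            D[i, j], D[i, i] = 1.0, -1.0
            N = ordered_double_frechet(A, Rmat, np.broadcast_to(D, (n, S, S)))
            arange = np.arange(n)[:, None]
            ordm[:, t1, :] = (
                N[arange, cols[None, :], rows[None, :]]
                - N[arange, rows[None, :], rows[None, :]]
            )
        B = ordm + np.swapaxes(ordm, 1, 2)  # full symmetric bilinear part

        S2 = B / p[:, None, None] - gq[:, :, None] * gq[:, None, :]
        w = _weight_tensor(params, sub.Z)
        w = _raw_scale_correction(params, qtau, w, scale)
        c = qtau[..., None] * w  # (n, T, 1+R): dA/dtheta_(t,k) = c * D_t
        H += np.einsum("ntk,num,ntu->tkum", c, c, S2, optimize=True).reshape(
            p_dep, p_dep
        )
        # curvature of A itself: block diagonal per transition
        curv = np.einsum("ntk,ntm,nt,nt->tkm", c, c, 1.0 / qtau, gq, optimize=True)
        if scale == "raw":
            # (q0, q0) curvature is zero on the raw scale
            corr = np.einsum("nt,nt->t", qtau / params.q0**2, gq)
            curv[:, 0, 0] -= corr
        for t in range(T):
            blk = slice(t * (1 + R), (t + 1) * (1 + R))
            H[blk, blk] += curv[t]

    L = _projection(params)
    if L is not None:
        H = L.T @ H @ L
    if n_excluded:
        warnings.warn(
            f"{n_excluded} intervals with degenerate transition probability "
            "excluded from the Hessian",
            stacklevel=3,
        )
    return H, n_excluded


def _hessian_pairwise(params: ParameterSet, dataset: PanelDataset, scale: str):
    """Direct quotient-rule assembly, one 4S-block exponential per pair."""
    ivs = dataset.intervals
    n_par = params.n_params
    H = np.zeros((n_par, n_par))
    n = ivs.tau.size
    q = intensities(params, ivs.Z)
    A = assemble_generators(params.structure, q) * ivs.tau[:, None, None]
    P = expm(A)
    pobs = P[np.arange(n), ivs.frm, ivs.to]
    ok = pobs >= PROB_FLOOR
    n_excluded = int((~ok).sum())
    for k in np.flatnonzero(ok):
        tau, z, s, sp = ivs.tau[k], ivs.Z[k], ivs.frm[k], ivs.to[k]
        p = pobs[k]
        dmats = [
            interval_dQ(params, tau, z, ell, scale=scale) for ell in range(n_par)
        ]
        dP = [frechet_derivative_expm(A[k], E)[s, sp] for E in dmats]
        for l1 in range(n_par):
            for l2 in range(l1, n_par):
                E12 = interval_d2Q(params, tau, z, l1, l2, scale=scale)
                d2P = second_frechet_expm(A[k], dmats[l1], dmats[l2], E12)[s, sp]
                val = d2P / p - dP[l1] * dP[l2] / p**2
                H[l1, l2] += val
                if l2 != l1:
                    H[l2, l1] += val
    return H, n_excluded


# ---------------------------------------------------------------------------
# power-series Hessian
# ---------------------------------------------------------------------------

def hessian_power_series(
    params: ParameterSet, dataset: PanelDataset, scale: str = "log_q0"
) -> HessianResult:
    """Hessian of the truncated-series log-likelihood.

    The per-interval likelihood entry is approximated by
    ``(I + A + A^2/2)[s, s']`` with ``A = Q tau``; its first and second
    derivatives in the rank-one base directions are short closed forms, so
    no matrix exponentials are needed.  Intervals where the truncated entry
    is not positive are excluded (and counted).
    """
    ivs = dataset.intervals
    T = params.structure.n_transitions
    R = params.R
    rows, cols = params.structure.rows, params.structure.cols
    S = params.structure.S
    p_dep = T * (1 + R)
    H = np.zeros((p_dep, p_dep))
    n_excluded = 0

    Dt = np.zeros((T, S, S))
    Dt[np.arange(T), rows, cols] = 1.0
    Dt[np.arange(T), rows, rows] -= 1.0

    for lo in range(0, ivs.tau.size, _CHUNK):
        sl = slice(lo, min(lo + _CHUNK, ivs.tau.size))
        sub = _Intervals(ivs.tau[sl], ivs.frm[sl], ivs.to[sl], ivs.Z[sl], ivs.subject[sl])
        n = sub.tau.size
        q = intensities(params, sub.Z)
        qtau = q * sub.tau[:, None]
        A = assemble_generators(params.structure, q) * sub.tau[:, None, None]
        arange = np.arange(n)
        eye_entry = (sub.frm == sub.to).astype(float)
        b = (
            eye_entry
            + A[arange, sub.frm, sub.to]
            + 0.5 * (A @ A)[arange, sub.frm, sub.to]
        )
        ok = b > 0
        n_excluded += int((~ok).sum())

        # first derivative of the truncated entry in direction D_t:
        #   D_t[s,s'] + (A D_t + D_t A)[s,s'] / 2
        D_ss = Dt[:, sub.frm, sub.to].T  # (n, T)
        A_row = A[arange, sub.frm, :]  # (n, S): A[s, :]
        A_col = A[arange, :, sub.to]  # (n, S): A[:, s']
        D_row = Dt[:, sub.frm, :].transpose(1, 0, 2)  # (n, T, S): D_t[s, :]
        D_col = Dt[:, :, sub.to].transpose(2, 0, 1)  # (n, T, S): D_t[:, s']
        AD = np.einsum("nk,ntk->nt", A_row, D_col)  # (A D_t)[s, s']
        DA = np.einsum("ntk,nk->nt", D_row, A_col)  # (D_t A)[s, s']
        db = D_ss + 0.5 * (AD + DA)  # (n, T)

        # second derivative in directions (D_a, D_b): (Da Db + Db Da)/2 entry
        DD = np.einsum("nak,nbk->nab", D_row, D_col)  # (Da Db)[s, s']
        d2b_pair = 0.5 * (DD + np.swapaxes(DD, 1, 2))  # (n, T, T)

        mask = ok.astype(float)
        binv = np.where(ok, 1.0 / np.where(ok, b, 1.0), 0.0)
        gq = db * binv[:, None]  # (n, T): d log b in direction D_t

        w = _weight_tensor(params, sub.Z)
        w = _raw_scale_correction(params, qtau, w, scale)
        c = qtau[..., None] * w

        S2 = d2b_pair * binv[:, None, None] - gq[:, :, None] * gq[:, None, :]
        S2 = S2 * mask[:, None, None]
        H += np.einsum("ntk,num,ntu->tkum", c, c, S2, optimize=True).reshape(
            p_dep, p_dep
        )
        # curvature of A (same closed forms as the exact route, but the
        # first-derivative functional is d log b instead of d log P)
        curv = np.einsum(
            "ntk,ntm,nt,nt->tkm", c, c, 1.0 / qtau, gq * mask[:, None], optimize=True
        )
        if scale == "raw":
            corr = np.einsum("nt,nt->t", qtau / params.q0**2, gq * mask[:, None])
            curv[:, 0, 0] -= corr
        for t in range(T):
            blk = slice(t * (1 + R), (t + 1) * (1 + R))
            H[blk, blk] += curv[t]

    L = _projection(params)
    if L is not None:
        H = L.T @ H @ L
    H = (H + H.T) / 2.0
    if n_excluded:
        warnings.warn(
            f"{n_excluded} intervals with nonpositive truncated entries "
            "excluded from the power-series Hessian",
            stacklevel=2,
        )
    return HessianResult(H=H, method="power_series", scale=scale, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Wald report
# ---------------------------------------------------------------------------

def wald_report(
    hess: HessianResult,
    params: ParameterSet,
    level: float = 0.95,
    hr_covariate_values: dict | None = None,
) -> CIReport:
    """Wald standard errors, confidence intervals, tests, and hazard ratios.

    The observed information is ``-H``; its inverse's diagonal gives
    squared standard errors on the fitting scale.  Baseline intensities
    fitted on the log scale are reported on the natural scale with
    delta-method SEs and exponentiated confidence limits.  Hazard ratios
    ``exp(z_r * beta_ij_r)`` are evaluated at ``z_r = 1`` unless
    ``hr_covariate_values`` supplies another covariate value.
    """
    info = -hess.H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        warnings.warn(
            "observed information is singular; using a pseudo-inverse",
            stacklevel=2,
        )
        cov = np.linalg.pinv(info)
    var = np.diag(cov).copy()
    if np.any(var < 0):
        warnings.warn(
            "negative variance estimates encountered (not at a proper "
            "maximum?); affected SEs are reported as NaN",
            stacklevel=2,
        )
        var[var < 0] = np.nan
    se_fit = np.sqrt(var)
    zcrit = norm.ppf(0.5 + level / 2.0)

    theta_fit = params.to_theta(hess.scale)
    labels = params.theta_labels()
    kinds, transitions, covs = _theta_metadata(params)

    rows = []
    for ell, lab in enumerate(labels):
        est_fit = theta_fit[ell]
        se = se_fit[ell]
        lo_fit, hi_fit = est_fit - zcrit * se, est_fit + zcrit * se
        if kinds[ell] == "q0" and hess.scale == "log_q0":
            est = float(np.exp(est_fit))
            se_nat = est * se  # delta method
            lo, hi = float(np.exp(lo_fit)), float(np.exp(hi_fit))
        else:
            est, se_nat, lo, hi = est_fit, se, lo_fit, hi_fit
        if kinds[ell] == "q0":
            zstat = est / se_nat if se_nat > 0 else np.nan
        else:
            zstat = est_fit / se if se > 0 else np.nan
        rows.append(
            dict(
                parameter=lab,
                kind=kinds[ell],
                transition=transitions[ell],
                covariate=covs[ell],
                estimate=est,
                se=se_nat,
                lo=lo,
                hi=hi,
                estimate_fit_scale=est_fit,
                se_fit_scale=se,
                lo_fit_scale=lo_fit,
                hi_fit_scale=hi_fit,
                z=zstat,
                reject=bool(abs(zstat) > zcrit) if np.isfinite(zstat) else False,
            )
        )
    table = pd.DataFrame(rows)

    hr_rows = []
    beta_rows = table[table.kind == "beta"]
    for _, r in beta_rows.iterrows():
        zval = 1.0
        if hr_covariate_values and r.covariate in hr_covariate_values:
            zval = float(hr_covariate_values[r.covariate])
        lo_b, hi_b = sorted((zval * r.lo, zval * r.hi))
        hr_rows.append(
            dict(
                transition=r.transition,
                covariate=r.covariate,
                at_value=zval,
                hr=float(np.exp(zval * r.estimate)),
                lo=float(np.exp(lo_b)),
                hi=float(np.exp(hi_b)),
            )
        )
    hazard_ratios = pd.DataFrame(hr_rows)
    return CIReport(table=table, hazard_ratios=hazard_ratios, level=level, method=hess.method)


def _theta_metadata(params: ParameterSet):
    kinds, transitions, covs = [], [], []
    pairs = params.structure.pairs
    if params.mode == TRANSITION_DEPENDENT:
        for i, j in pairs:
            kinds.append("q0")
            transitions.append(f"{i}->{j}")
            covs.append(None)
            for c in params.covariate_names:
                kinds.append("beta")
                transitions.append(f"{i}->{j}")
                covs.append(c)
    else:
        for i, j in pairs:
            kinds.append("q0")
            transitions.append(f"{i}->{j}")
            covs.append(None)
        for c in params.covariate_names:
            kinds.append("beta")
            transitions.append("all")
            covs.append(c)
    return kinds, transitions, covs
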