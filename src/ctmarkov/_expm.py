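"""Batched matrix exponentials and their directional (Fréchet) derivatives.

Everything in this package that touches a transition-probability matrix goes
through :func:`expm`, a scaling-and-squaring Padé-13 evaluation that operates
on stacks of matrices ``(..., n, n)`` at once.  Panel likelihoods need one
matrix exponential per observation interval, so the batched form is the
difference between a usable fit and an unusable one.

Directional derivatives are obtained from exponentials of block upper
triangular matrices:

* ``expm([[A, E], [0, A]])`` carries ``∫₀¹ e^{uA} E e^{(1-u)A} du`` in its
  upper-right block — the first Fréchet derivative of ``e^A`` in direction
  ``E``.
* a doubly nested version of the same construction yields the second
  derivative (see :func:`second_frechet_expm`), and a 3-block chain yields
  the ordered double integral used when assembling Hessians over many
  direction pairs.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "expm",
    "frechet_derivative_expm",
    "expm_and_frechet",
    "ordered_double_frechet",
    "second_frechet_expm",
]

# Padé-13 coefficients (numerator of the [13/13] diagonal approximant).
_B13 = np.array(
    [
        64764752532480000.0,
        32382376266240000.0,
        7771770303897600.0,
        1187353796428800.0,
        129060195264000.0,
        10559470521600.0,
        670442572800.0,
        33522128640.0,
        1323241920.0,
        40840800.0,
        960960.0,
        16380.0,
        182.0,
        1.0,
    ]
)
# 1-norm threshold below which the [13/13] approximant is accurate to
# double precision without scaling (Higham 2005).
_THETA13 = 5.371920351148152


def expm(a: np.ndarray) -> np.ndarray:
    """Matrix exponential of a stack of square matrices.

    Parameters
    ----------
    a
        Array of shape ``(..., n, n)``.

    Returns
    -------
    Array of the same shape, ``exp(a)`` applied to the trailing two axes.

    Notes
    -----
    Scaling and squaring with a shared scaling exponent across the batch:
    the exponent is chosen from the largest 1-norm in the stack, so every
    member is at or below the Padé-13 accuracy threshold.  Squaring is a
    batched matmul and therefore cheap even when one outlier forces a few
    extra squarings on the whole stack.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim < 2 or a.shape[-1] != a.shape[-2]:
        raise ValueError(f"expected (..., n, n) square matrices, got shape {a.shape}")
    n = a.shape[-1]
    if a.size == 0:
        return a.copy()

    norm1 = np.abs(a).sum(axis=-2).max(axis=-1)  # 1-norm per matrix
    max_norm = float(norm1.max())
    s = 0
    if max_norm > _THETA13:
        s = int(np.ceil(np.log2(max_norm / _THETA13)))
    a_s = a / (2.0**s) if s else a

    ident = np.broadcast_to(np.eye(n), a.shape)
    a2 = a_s @ a_s
    a4 = a2 @ a2
    a6 = a2 @ a4
    b = _B13
    u = a_s @ (
        a6 @ (b[13] * a6 + b[11] * a4 + b[9] * a2)
        + b[7] * a6
        + b[5] * a4
        + b[3] * a2
        + b[1] * ident
    )
    v = (
        a6 @ (b[12] * a6 + b[10] * a4 + b[8] * a2)
        + b[6] * a6
        + b[4] * a4
        + b[2] * a2
        + b[0] * ident
    )
    x = np.linalg.solve(v - u, v + u)
    for _ in range(s):
        x = x @ x
    return x


def _block2(a: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Assemble ``[[A, E], [0, A]]`` batched."""
    n = a.shape[-1]
    out = np.zeros(a.shape[:-2] + (2 * n, 2 * n), dtype=float)
    out[..., :n, :n] = a
    out[..., :n, n:] = e
    out[..., n:, n:] = a
    return out


def frechet_derivative_expm(a: np.ndarray, adot: np.ndarray) -> np.ndarray:
    """Directional derivative of the matrix exponential.

    Returns ``d/dh exp(A + h·Ȧ) |_{h=0} = ∫₀¹ e^{uA} Ȧ e^{(1-u)A} du``,
    read off as the upper-right ``n×n`` block of ``exp([[A, Ȧ], [0, A]])``.
    Accepts stacks ``(..., n, n)`` in both arguments.
    """
    a = np.asarray(a, dtype=float)
    adot = np.asarray(adot, dtype=float)
    if a.shape != adot.shape:
        raise ValueError(f"A and Adot shapes differ: {a.shape} vs {adot.shape}")
    n = a.shape[-1]
    big = expm(_block2(a, adot))
    return np.ascontiguousarray(big[..., :n, n:])


def expm_and_frechet(a: np.ndarray, adot: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """``exp(A)`` and its Fréchet derivative from a single block exponential.

    The diagonal blocks of ``exp([[A, E], [0, A]])`` are ``exp(A)``, so both
    quantities come at the cost of one ``2n×2n`` exponential.
    """
    a = np.asarray(a, dtype=float)
    adot = np.asarray(adot, dtype=float)
    n = a.shape[-1]
    big = expm(_block2(a, adot))
    return (
        np.ascontiguousarray(big[..., :n, :n]),
        np.ascontiguousarray(big[..., :n, n:]),
    )


def ordered_double_frechet(a: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    """Ordered second-order integral ``∫∫_{u+v+w=1} e^{uA} E₁ e^{vA} E₂ e^{wA}``.

    Upper-right block of the chained construction
    ``exp([[A, E₁, 0], [0, A, E₂], [0, 0, A]])``.  The symmetric second
    Fréchet derivative of ``exp`` (without curvature of ``A`` itself) is
    ``ordered(E₁, E₂) + ordered(E₂, E₁)``.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[-1]
    big = np.zeros(a.shape[:-2] + (3 * n, 3 * n), dtype=float)
    big[..., :n, :n] = a
    big[..., n : 2 * n, n : 2 * n] = a
    big[..., 2 * n :, 2 * n :] = a
    big[..., :n, n : 2 * n] = e1
    big[..., n : 2 * n, 2 * n :] = e2
    return np.ascontiguousarray(expm(big)[..., :n, 2 * n :])


def second_frechet_expm(
    a: np.ndarray,
    e1: np.ndarray,
    e2: np.ndarray,
    e12: np.ndarray | None = None,
) -> np.ndarray:
    """Second derivative of the matrix exponential along a parametrized path.

    For ``A(θ)`` with first-order variations ``E₁ = ∂A/∂θ₁``,
    ``E₂ = ∂A/∂θ₂`` and cross-curvature ``E₁₂ = ∂²A/∂θ₁∂θ₂``, returns
    ``∂²/∂θ₁∂θ₂ exp(A)``.  Computed by differentiating the first-derivative
    block construction once more: with ``C₁ = [[A, E₁], [0, A]]`` and
    ``C₂ = [[E₂, E₁₂], [0, E₂]]``, the answer is rows ``0:n`` and columns
    ``3n:4n`` of ``exp([[C₁, C₂], [0, C₁]])``.

    ``E₁₂ = None`` means the two parameters enter ``A`` without interaction
    (zero cross-curvature).
    """
    a = np.asarray(a, dtype=float)
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if not (a.shape == e1.shape == e2.shape):
        raise ValueError("A, E1, E2 must share one shape")
    if e12 is None:
        e12 = np.zeros_like(a)
    else:
        e12 = np.asarray(e12, dtype=float)
        if e12.shape != a.shape:
            raise ValueError("E12 shape mismatch")
    n = a.shape[-1]
    big = np.zeros(a.shape[:-2] + (4 * n, 4 * n), dtype=float)
    # C1 on both diagonal 2n-blocks
    for off in (0, 2 * n):
        big[..., off : off + n, off : off + n] = a
        big[..., off : off + n, off + n : off + 2 * n] = e1
        big[..., off + n : off + 2 * n, off + n : off + 2 * n] = a
    # C2 in the upper-right 2n-block
    big[..., :n, 2 * n : 3 * n] = e2
    big[..., :n, 3 * n :] = e12
    big[..., n : 2 * n, 3 * n :] = e2
    return np.ascontiguousarray(expm(big)[..., :n, 3 * n :])
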