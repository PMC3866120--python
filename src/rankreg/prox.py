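"""Spectral primitives shared by the low-rank solvers.

The nuclear norm (trace norm) of a matrix is the sum of its singular
values; it is the tightest convex surrogate of matrix rank and the
regularizer used throughout this package.  Its proximal operator is
singular-value soft-thresholding (SVT).  The quadratic-surrogate value
and the momentum recursion are the bookkeeping pieces of the accelerated
proximal-gradient (FISTA) scheme with backtracking.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

__all__ = [
    "SvdTriple",
    "thin_svd",
    "nuclear_norm",
    "svt",
    "soft_threshold",
    "surrogate_value",
    "momentum_update",
]


class SvdTriple(NamedTuple):
    """Thin singular value decomposition M = U @ diag(s) @ Vt."""

    left_vectors: np.ndarray
    singular_values: np.ndarray
    right_vectors_t: np.ndarray


def _as_finite_array(M, name: str = "matrix") -> np.ndarray:
    A = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError(f"{name} contains non-finite entries")
    return A


def thin_svd(M) -> SvdTriple:
    """Thin SVD with singular values sorted in non-increasing order."""
    A = _as_finite_array(M)
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    return SvdTriple(U, s, Vt)


def nuclear_norm(M) -> float:
    """Sum of singular values of ``M`` (the trace norm)."""
    A = _as_finite_array(M)
    if A.size == 0:
        return 0.0
    return float(np.linalg.svd(A, compute_uv=False).sum())


def svt(Z, tau: float) -> np.ndarray:
    """Singular-value soft-thresholding: prox of ``tau * nuclear_norm``.

    Returns the unique minimizer of ``(1/2)||W - Z||_F^2 + tau ||W||_*``,
    obtained by shrinking each singular value of ``Z`` by ``tau`` and
    flooring at zero.
    """
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    A = _as_finite_array(Z, "Z")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    s_shrunk = np.maximum(s - tau, 0.0)
    return (U * s_shrunk) @ Vt


def soft_threshold(v, tau: float) -> np.ndarray:
    """Entrywise soft-threshold: prox of ``tau * l1-norm``."""
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    a = _as_finite_array(v, "v")
    return np.sign(a) * np.maximum(np.abs(a) - tau, 0.0)


def surrogate_value(
    candidate,
    anchor,
    smooth_value_at_anchor: float,
    gradient_at_anchor,
    lipschitz_estimate: float,
    lam: float,
) -> float:
    """Quadratic majorizer Q_L(candidate, anchor) used by backtracking.

    Q = f(anchor) + <grad, c - a> + (L/2)||c - a||_F^2 + lam ||c||_*.
    When L is at least the Lipschitz constant of the gradient of the
    smooth part, Q upper-bounds the true objective at ``candidate``.
    """
    if lipschitz_estimate <= 0:
        raise ValueError("lipschitz_estimate must be positive")
    C = _as_finite_array(candidate, "candidate")
    A = _as_finite_array(anchor, "anchor")
    G = _as_finite_array(gradient_at_anchor, "gradient")
    D = C - A
    return (
        float(smooth_value_at_anchor)
        + float(np.vdot(G, D))
        + 0.5 * lipschitz_estimate * float(np.vdot(D, D))
        + lam * nuclear_norm(C)
    )


def momentum_update(t_k: float) -> float:
    """FISTA momentum recursion t_{k+1} = (1 + sqrt(1 + 4 t_k^2)) / 2."""
    if t_k < 1:
        raise ValueError(f"momentum parameter must be >= 1, got {t_k}")
    return (1.0 + math.sqrt(1.0 + 4.0 * t_k * t_k)) / 2.0
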