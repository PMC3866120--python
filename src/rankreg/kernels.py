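"""Mercer kernels, Gram matrices and the PSD matrix square root.

Families: linear, gaussian (RBF), inhomogeneous polynomial, and the
ANOVA kernel of order d with a per-coordinate Gaussian base

    K(x, z) = sum over size-d subsets S of prod_{j in S} exp(-(x_j-z_j)^2 / (2 h^2)),

computed by the Newton-Girard recursion between elementary symmetric
polynomials and power sums of the per-coordinate base kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KernelSpec",
    "kernel_eval",
    "gram_matrix",
    "psd_sqrt",
    "psd_sqrt_pinv",
    "median_bandwidth",
    "resolve_bandwidth",
]

_FAMILIES = ("linear", "gaussian", "polynomial", "anova")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    bandwidth is the Gaussian length scale h (also the ANOVA base
    kernel's); degree applies to the polynomial family; order is the
    ANOVA subset size d.
    """

    family: str = "linear"
    bandwidth: float | None = 1.0
    degree: int = 3
    order: int = 2

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; choose from {_FAMILIES}")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive (or None for the median heuristic)")
        if self.degree < 1 or int(self.degree) != self.degree:
            raise ValueError("degree must be a positive integer")
        if self.order < 1 or int(self.order) != self.order:
            raise ValueError("order must be a positive integer")


def _anova_gram(spec: KernelSpec, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    # per-coordinate Gaussian base kernels B_j(i, k) = exp(-(X_ij - Z_kj)^2 / 2h^2)
    h2 = 2.0 * spec.bandwidth**2
    d = spec.order
    p = X.shape[1]
    if d > p:
        raise ValueError(f"anova order {d} exceeds dimension {p}")
    diff = X[:, None, :] - Z[None, :, :]
    B = np.exp(-(diff**2) / h2)  # n x m x p
    # Newton-Girard: e_d from power sums P_k = sum_j B_j^k (elementwise over pairs)
    P = [np.sum(B**k, axis=2) for k in range(1, d + 1)]
    E = [np.ones(B.shape[:2])]
    for dd in range(1, d + 1):
        acc = np.zeros(B.shape[:2])
        for k in range(1, dd + 1):
            acc += ((-1) ** (k - 1)) * E[dd - k] * P[k - 1]
        E.append(acc / dd)
    return E[d]


def gram_matrix(spec: KernelSpec, X, Z=None) -> np.ndarray:
    """Kernel matrix K with K[i, j] = k(X[i], Z[j]); Z defaults to X.

    With Z omitted the result is symmetrized to remove floating-point
    asymmetry.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    symmetric = Z is None
    Z = X if symmetric else np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Z.shape[1]}")
    if spec.family in ("gaussian", "anova") and spec.bandwidth is None:
        raise ValueError(
            "bandwidth is unresolved (None); call resolve_bandwidth(spec, X_train) first"
        )
    if spec.family == "linear":
        K = X @ Z.T
    elif spec.family == "gaussian":
        sq = cdist(X, Z, "sqeuclidean")
        K = np.exp(-sq / (2.0 * spec.bandwidth**2))
    elif spec.family == "polynomial":
        K = (1.0 + X @ Z.T) ** spec.degree
    else:
        K = _anova_gram(spec, X, Z)
    if symmetric:
        K = 0.5 * (K + K.T)
    return K


def kernel_eval(spec: KernelSpec, x, z) -> float:
    """Kernel value k(x, z) for two regulator-expression vectors."""
    x = np.asarray(x, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    if x.shape != z.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {z.shape[0]}")
    return float(gram_matrix(spec, x[None, :], z[None, :])[0, 0])


def resolve_bandwidth(spec: KernelSpec, X) -> KernelSpec:
    """Fill in an unset bandwidth from the training regulators.

    Gaussian: median pairwise distance heuristic.  ANOVA: unit
    bandwidth, the natural per-coordinate scale for standardized
    expression.  Other families are returned unchanged.
    """
    if spec.bandwidth is not None or spec.family in ("linear", "polynomial"):
        return spec
    if spec.family == "gaussian":
        return replace(spec, bandwidth=median_bandwidth(X))
    return replace(spec, bandwidth=1.0)


def median_bandwidth(X) -> float:
    """Median pairwise Euclidean distance heuristic for the bandwidth."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = cdist(X, X)
    vals = d[np.triu_indices_from(d, k=1)]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 1.0
    return float(np.median(vals))


def _check_symmetric(K, tol: float = 1e-8) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("K must be square")
    denom = max(1.0, float(np.abs(K).max()))
    if np.abs(K - K.T).max() > tol * denom:
        raise ValueError("K is not symmetric")
    return 0.5 * (K + K.T)


def psd_sqrt(K) -> np.ndarray:
    """Principal square root of a symmetric PSD matrix.

    Eigenvalues below zero (numerical noise) are clipped before taking
    square roots; gross asymmetry raises.
    """
    K = _check_symmetric(K)
    w, V = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    S = (V * np.sqrt(w)) @ V.T
    return 0.5 * (S + S.T)


def psd_sqrt_pinv(K, rel_cut: float = 1e-10) -> np.ndarray:
    """Pseudo-inverse of the principal square root of PSD K.

    Eigenvalues below rel_cut * lambda_max are treated as exactly zero,
    anticipating rank-deficient Gram matrices.
    """
    K = _check_symmetric(K)
    w, V = np.linalg.eigh(K)
    w = np.clip(w, 0.0, None)
    cut = rel_cut * (w.max() if w.size else 0.0)
    inv_sqrt = np.where(w > cut, 1.0 / np.sqrt(np.where(w > cut, w, 1.0)), 0.0)
    S = (V * inv_sqrt) @ V.T
    return 0.5 * (S + S.T)
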