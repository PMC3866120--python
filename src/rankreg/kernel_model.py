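"""Nonlinear (kernelized) low-rank model.

Each target's regulation function f_l lives in the RKHS of a Mercer
kernel; the functions are constrained to share a low-dimensional
subspace by penalizing the sum of singular values of the function
system (the trace of the square root of the L x L Gram of the f_l's).
By the representer theorem f_l(x) = sum_i a_il k(x, x_i), and the
penalty on the n x L coefficient matrix A becomes ||K^{1/2} A||_*, so

    min_A (1/2)||Y - K A||_F^2 + lambda ||K^{1/2} A||_*.

Substituting B = K^{1/2} A turns this into a plain nuclear-norm
problem with design matrix K^{1/2}, solved by the same accelerated
proximal-gradient engine as the linear model; A is recovered through
the pseudo-inverse of K^{1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fista import fista
from .kernels import KernelSpec, gram_matrix, psd_sqrt, psd_sqrt_pinv
from .linear import estimate_rank
from .prox import nuclear_norm, svt

__all__ = [
    "KernelFitResult",
    "function_gram",
    "kernel_objective",
    "fit_kernel_lowrank",
    "predict_kernel",
]


@dataclass
class KernelFitResult:
    """Fitted kernel low-rank model.

    representer_coefficients (A, n x L) weight the kernel sections at
    the training samples; reparameterized_solution (B = K^{1/2} A) is
    the variable the solver works in.
    """

    representer_coefficients: np.ndarray
    reparameterized_solution: np.ndarray
    gram: np.ndarray
    gram_sqrt: np.ndarray
    lam: float
    objective_trace: np.ndarray
    estimated_rank: int
    converged: bool
    iterations: int
    lipschitz: float


def function_gram(A, K) -> np.ndarray:
    """L x L Gram G of the fitted functions: G = A^T K A.

    G[l, l'] is the RKHS inner product <f_l, f_l'>; the low-rank
    penalty equals trace(G^{1/2}).
    """
    A = np.asarray(A, dtype=float)
    K = np.asarray(K, dtype=float)
    G = A.T @ K @ A
    return 0.5 * (G + G.T)


def kernel_objective(A, K, Y, lam: float, gram_sqrt=None) -> float:
    """(1/2)||Y - K A||_F^2 + lam ||K^{1/2} A||_*."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    A = np.asarray(A, dtype=float)
    K = np.asarray(K, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = K.shape[0]
    if K.shape != (n, n) or A.shape[0] != n or Y.shape != (n, A.shape[1]):
        raise ValueError(
            f"shape mismatch: K {K.shape}, A {A.shape}, Y {Y.shape}"
        )
    S = psd_sqrt(K) if gram_sqrt is None else np.asarray(gram_sqrt, dtype=float)
    R = Y - K @ A
    return 0.5 * float(np.vdot(R, R)) + lam * nuclear_norm(S @ A)


def fit_kernel_lowrank(
    K,
    Y,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 5000,
    eta: float = 2.0,
    L0: float = 1.0,
    B0=None,
    rank_tol: float = 1e-8,
) -> KernelFitResult:
    """Fit the representer coefficients by solving the B-problem.

    min_B (1/2)||Y - K^{1/2} B||_F^2 + lam ||B||_*, then
    A = pinv(K^{1/2}) B.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    K = np.asarray(K, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = K.shape[0]
    if Y.ndim != 2 or Y.shape[0] != n:
        raise ValueError(f"Y must have {n} rows, got {Y.shape}")
    S = psd_sqrt(K)
    L_targets = Y.shape[1]

    StY = S @ Y  # S is symmetric
    yy = float(np.vdot(Y, Y))

    def smooth(B):
        return 0.5 * (yy - 2.0 * float(np.vdot(B, StY)) + float(np.vdot(B, K @ B)))

    def grad(B):
        # S^T (S B - Y) = K B - S Y
        return K @ B - StY

    def prox(Z, step):
        return svt(Z, lam * step)

    def penalty(B):
        return lam * nuclear_norm(B)

    x0 = np.zeros((n, L_targets)) if B0 is None else np.asarray(B0, dtype=float)
    res = fista(smooth, grad, prox, penalty, x0, tol=tol, max_iter=max_iter, eta=eta, L0=L0)
    B = res.x
    A = psd_sqrt_pinv(K) @ B
    return KernelFitResult(
        representer_coefficients=A,
        reparameterized_solution=B,
        gram=K,
        gram_sqrt=S,
        lam=float(lam),
        objective_trace=res.objective_trace,
        estimated_rank=estimate_rank(B, rank_tol),
        converged=res.converged,
        iterations=res.iterations,
        lipschitz=res.lipschitz,
    )


def predict_kernel(fit, spec: KernelSpec, X_train, X_new) -> np.ndarray:
    """Representer-form predictions: K_cross @ A with
    K_cross[j, i] = k(x_new_j, x_train_i)."""
    A = fit.representer_coefficients if isinstance(fit, KernelFitResult) else np.asarray(fit, dtype=float)
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_train.shape[0] != A.shape[0]:
        raise ValueError(
            f"A has {A.shape[0]} rows but X_train has {X_train.shape[0]} samples"
        )
    K_cross = gram_matrix(spec, X_new, X_train)
    return K_cross @ A
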