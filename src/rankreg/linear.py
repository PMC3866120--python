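"""Linear low-rank model for gene expression programs.

Fits the p x L coefficient matrix W in the multi-target regression
Y ~ X W by minimizing

    (1/2) ||Y - X W||_F^2 + lambda ||W||_*

where X (n samples x p regulators) and Y (n x L targets) hold
standardized expression values and ||.||_* is the nuclear norm.  The
rank of W counts the independent regulatory modules shared by the
targets; the nuclear norm is its convex surrogate.  The solver is
accelerated proximal gradient with backtracking and singular-value
thresholding as the prox step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fista import fista
from .prox import nuclear_norm, svt

__all__ = [
    "LinearFitResult",
    "linear_objective",
    "fit_linear_lowrank",
    "predict_linear",
    "estimate_rank",
]


@dataclass
class LinearFitResult:
    """Fitted linear low-rank model.

    coefficients is the p x L weight matrix W; column l holds the
    regulator weights for target l.  estimated_rank counts singular
    values of W above a relative spectral cutoff.
    """

    coefficients: np.ndarray
    lam: float
    objective_trace: np.ndarray
    estimated_rank: int
    converged: bool
    iterations: int
    lipschitz: float

    def predict(self, X_new) -> np.ndarray:
        return predict_linear(self.coefficients, X_new)


def _check_xy(X, Y):
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D (samples x variables)")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"X and Y must have the same number of samples (rows); "
            f"got {X.shape[0]} and {Y.shape[0]}"
        )
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("X and Y must be finite")
    return X, Y


def linear_objective(W, X, Y, lam: float) -> float:
    """(1/2)||Y - X W||_F^2 + lam ||W||_*."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X, Y = _check_xy(X, Y)
    W = np.asarray(W, dtype=float)
    if W.shape != (X.shape[1], Y.shape[1]):
        raise ValueError(
            f"W must be {X.shape[1]} x {Y.shape[1]}, got {W.shape}"
        )
    R = Y - X @ W
    return 0.5 * float(np.vdot(R, R)) + lam * nuclear_norm(W)


def fit_linear_lowrank(
    X,
    Y,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 5000,
    eta: float = 2.0,
    L0: float = 1.0,
    W0=None,
    rank_tol: float = 1e-8,
) -> LinearFitResult:
    """Solve the nuclear-norm regularized least-squares problem for W.

    W0 provides a warm start (defaults to the zero matrix, the exact
    solution for lambda >= sigma_max(X^T Y)).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X, Y = _check_xy(X, Y)
    n, p = X.shape
    L_targets = Y.shape[1]

    # cache the Gram pieces: grad f(W) = XtX W - XtY
    XtX = X.T @ X
    XtY = X.T @ Y
    yy = float(np.vdot(Y, Y))

    def smooth(W):
        # 0.5*||Y - XW||^2 via the Gram expansion
        return 0.5 * (yy - 2.0 * float(np.vdot(W, XtY)) + float(np.vdot(W, XtX @ W)))

    def grad(W):
        return XtX @ W - XtY

    def prox(Z, step):
        return svt(Z, lam * step)

    def penalty(W):
        return lam * nuclear_norm(W)

    x0 = np.zeros((p, L_targets)) if W0 is None else np.asarray(W0, dtype=float)
    res = fista(smooth, grad, prox, penalty, x0, tol=tol, max_iter=max_iter, eta=eta, L0=L0)
    return LinearFitResult(
        coefficients=res.x,
        lam=float(lam),
        objective_trace=res.objective_trace,
        estimated_rank=estimate_rank(res.x, rank_tol),
        converged=res.converged,
        iterations=res.iterations,
        lipschitz=res.lipschitz,
    )


def predict_linear(W, X_new) -> np.ndarray:
    """Predictions X_new @ W for new samples."""
    W = np.asarray(W, dtype=float)
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or W.ndim != 2 or X_new.shape[1] != W.shape[0]:
        raise ValueError(
            f"X_new columns ({X_new.shape}) must match W rows ({W.shape})"
        )
    return X_new @ W


def estimate_rank(M, rel_tol: float = 1e-8) -> int:
    """Count singular values above rel_tol * sigma_max(M)."""
    if not (0 < rel_tol < 1):
        raise ValueError("rel_tol must lie in (0, 1)")
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        return 0
    s = np.linalg.svd(M, compute_uv=False)
    if s[0] == 0:
        return 0
    return int(np.count_nonzero(s > rel_tol * s[0]))
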