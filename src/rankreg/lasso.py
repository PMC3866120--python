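"""Per-target L1-regularized least squares (the Lasso baseline).

Each target gene is fit independently:

    min_{w_l} (1/2)||y_l - X w_l||^2 + lambda ||w_l||_1

The problem is separable across targets, so all L columns are solved in
one matrix-valued run of the shared accelerated proximal-gradient
engine with the entrywise soft-threshold as the prox step; the result
is identical to L independent fits.  A per-target lambda vector is also
accepted, in which case the prox thresholds each column at its own
level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fista import fista
from .linear import _check_xy
from .prox import soft_threshold

__all__ = ["LassoFitResult", "soft_threshold", "fit_lasso", "lasso_objective"]


@dataclass
class LassoFitResult:
    """Fitted Lasso coefficients (p regulators x L targets)."""

    coefficients: np.ndarray
    lam: np.ndarray  # scalar broadcast to per-target vector
    nonzero_counts: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    iterations: int

    def predict(self, X_new) -> np.ndarray:
        return np.asarray(X_new, dtype=float) @ self.coefficients


def lasso_objective(W, X, Y, lam) -> float:
    """Sum over targets of (1/2)||y_l - X w_l||^2 + lam_l ||w_l||_1."""
    X, Y = _check_xy(X, Y)
    W = np.asarray(W, dtype=float)
    lam_vec = np.broadcast_to(np.asarray(lam, dtype=float), (Y.shape[1],))
    R = Y - X @ W
    return 0.5 * float(np.vdot(R, R)) + float(np.sum(lam_vec * np.abs(W).sum(axis=0)))


def fit_lasso(
    X,
    Y,
    lam,
    tol: float = 1e-8,
    max_iter: int = 5000,
    eta: float = 2.0,
    L0: float = 1.0,
    W0=None,
) -> LassoFitResult:
    """Fit all targets' L1-regularized regressions jointly.

    lam may be a scalar (shared across targets, the default protocol)
    or a length-L vector of per-target penalties.
    """
    X, Y = _check_xy(X, Y)
    n, p = X.shape
    L_targets = Y.shape[1]
    lam_vec = np.broadcast_to(np.asarray(lam, dtype=float), (L_targets,)).copy()
    if np.any(lam_vec < 0):
        raise ValueError("lambda must be non-negative")

    XtX = X.T @ X
    XtY = X.T @ Y
    yy = float(np.vdot(Y, Y))

    def smooth(W):
        return 0.5 * (yy - 2.0 * float(np.vdot(W, XtY)) + float(np.vdot(W, XtX @ W)))

    def grad(W):
        return XtX @ W - XtY

    def prox(Z, step):
        tau = lam_vec * step  # per-column threshold
        return np.sign(Z) * np.maximum(np.abs(Z) - tau[None, :], 0.0)

    def penalty(W):
        return float(np.sum(lam_vec * np.abs(W).sum(axis=0)))

    x0 = np.zeros((p, L_targets)) if W0 is None else np.asarray(W0, dtype=float)
    res = fista(smooth, grad, prox, penalty, x0, tol=tol, max_iter=max_iter, eta=eta, L0=L0)
    W = res.x
    return LassoFitResult(
        coefficients=W,
        lam=lam_vec,
        nonzero_counts=np.count_nonzero(W, axis=0),
        objective_trace=res.objective_trace,
        converged=res.converged,
        iterations=res.iterations,
    )
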