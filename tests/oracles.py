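"""Independent reference computations used to check the solvers.

Everything here deliberately avoids the package's optimized code paths:
the prox oracle is plain subgradient descent, the solver references are
unaccelerated proximal gradient with exact Lipschitz steps, and the
objective oracles are naive loops.
"""

from __future__ import annotations

import numpy as np


def nuclear_norm_loops(M) -> float:
    """Trace of the principal square root of M^T M via eigendecomposition."""
    M = np.asarray(M, dtype=float)
    w = np.linalg.eigvalsh(M.T @ M)
    return float(np.sqrt(np.clip(w, 0.0, None)).sum())


def prox_objective(W, Z, tau) -> float:
    # one evaluator for both sides of any comparison; SVD-based singular
    # values are accurate near zero where the Gram-eigenvalue route loses
    # ~sqrt(eps) on a thresholded (exactly rank-deficient) matrix
    nn = float(np.linalg.svd(np.asarray(W, dtype=float), compute_uv=False).sum())
    return 0.5 * float(np.sum((W - Z) ** 2)) + tau * nn


def subgradient_prox_oracle(Z, tau, steps=2000):
    """Minimize (1/2)||W - Z||_F^2 + tau ||W||_* by subgradient descent.

    U V^T from the thin SVD of W is a valid subgradient of the nuclear
    norm for every W.  Diminishing steps, best iterate kept.
    """
    Z = np.asarray(Z, dtype=float)
    W = Z.copy()
    best = prox_objective(W, Z, tau)
    best_W = W.copy()
    alpha0 = 0.5 * max(1.0, float(np.linalg.norm(Z, 2)))
    for k in range(steps):
        U, s, Vt = np.linalg.svd(W, full_matrices=False)
        g = (W - Z) + tau * (U @ Vt)
        W = W - (alpha0 / np.sqrt(k + 1.0)) * g
        obj = prox_objective(W, Z, tau)
        if obj < best:
            best = obj
            best_W = W.copy()
    return best_W, best


def _svt(Z, tau):
    U, s, Vt = np.linalg.svd(np.asarray(Z, dtype=float), full_matrices=False)
    return (U * np.maximum(s - tau, 0.0)) @ Vt


def ista_linear_reference(X, Y, lam, rel_change=1e-12, max_iter=200_000):
    """Plain (unaccelerated) proximal gradient for the linear low-rank
    problem, exact Lipschitz step, run to a tiny objective change."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    XtX = X.T @ X
    XtY = X.T @ Y
    L = float(np.linalg.eigvalsh(XtX)[-1])
    W = np.zeros((X.shape[1], Y.shape[1]))

    def obj(W):
        R = Y - X @ W
        return 0.5 * float(np.sum(R * R)) + lam * nuclear_norm_loops(W)

    prev = obj(W)
    for _ in range(max_iter):
        W = _svt(W - (XtX @ W - XtY) / L, lam / L)
        cur = obj(W)
        if abs(prev - cur) <= rel_change * max(1.0, abs(cur)):
            break
        prev = cur
    return W, obj(W)


def ista_kernel_reference(S, Y, lam, rel_change=1e-12, max_iter=200_000):
    """Same reference for the reparameterized kernel problem
    min_B (1/2)||Y - S B||_F^2 + lam ||B||_* with S = K^{1/2}."""
    return ista_linear_reference(S, Y, lam, rel_change=rel_change, max_iter=max_iter)


def lstsq_objective_loops(W, X, Y, lam) -> float:
    """Naive summation version of the linear low-rank objective."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    total = 0.0
    for i in range(X.shape[0]):
        for l in range(Y.shape[1]):
            pred = 0.0
            for j in range(X.shape[1]):
                pred += X[i, j] * W[j, l]
            total += (Y[i, l] - pred) ** 2
    return 0.5 * total + lam * nuclear_norm_loops(W)


def rmse_loops(P, O):
    """Per-target RMSE via explicit loops."""
    P = np.asarray(P, dtype=float)
    O = np.asarray(O, dtype=float)
    out = []
    for l in range(P.shape[1]):
        acc = 0.0
        for i in range(P.shape[0]):
            acc += (P[i, l] - O[i, l]) ** 2
        out.append((acc / P.shape[0]) ** 0.5)
    return np.asarray(out)


def soft_threshold_grid_oracle(v, tau, resolution=1e-4):
    """Per-coordinate grid search for argmin (1/2)(w - v)^2 + tau |w|."""
    v = np.asarray(v, dtype=float)
    out = np.empty_like(v)
    for i, vi in enumerate(v):
        span = abs(vi) + tau + 1.0
        grid = np.arange(-span, span, resolution)
        vals = 0.5 * (grid - vi) ** 2 + tau * np.abs(grid)
        out[i] = grid[np.argmin(vals)]
    return out
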