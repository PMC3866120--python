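"""Accelerated proximal-gradient (FISTA) engine with backtracking.

One engine drives all three models in this package; they differ only in
the smooth part (a least-squares loss against a design matrix) and the
proximal operator (singular-value thresholding for the nuclear norm,
entrywise soft-thresholding for the Lasso).

The backtracking line search finds the smallest L = eta^i * L_{k-1}
such that the smooth part satisfies its quadratic upper bound at the
prox point, then takes the proximal step of size 1/L and extrapolates
with the standard momentum sequence t_{k+1} = (1 + sqrt(1+4 t_k^2))/2,
y = x_k + ((t_k - 1)/t_{k+1})(x_k - x_{k-1}).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .prox import momentum_update

__all__ = ["FistaResult", "fista"]


@dataclass
class FistaResult:
    """Outcome of one accelerated proximal-gradient run."""

    x: np.ndarray
    objective_trace: np.ndarray
    lipschitz: float
    converged: bool
    iterations: int


def fista(
    smooth: Callable[[np.ndarray], float],
    grad: Callable[[np.ndarray], np.ndarray],
    prox: Callable[[np.ndarray, float], np.ndarray],
    penalty: Callable[[np.ndarray], float],
    x0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 5000,
    eta: float = 2.0,
    L0: float = 1.0,
) -> FistaResult:
    """Minimize smooth(x) + penalty(x) where prox(z, s) solves the
    penalty's proximal problem with step s.

    tol is the relative objective-change stopping threshold; hitting
    max_iter returns the last iterate flagged not-converged rather than
    raising.
    """
    if eta <= 1:
        raise ValueError("backtracking factor eta must exceed 1")
    if L0 <= 0:
        raise ValueError("initial Lipschitz estimate must be positive")
    x = np.array(x0, dtype=float)
    x_prev = x.copy()
    y = x.copy()
    t = 1.0
    L = float(L0)

    obj = smooth(x) + penalty(x)
    trace = [obj]
    converged = False
    iterations = 0

    for k in range(max_iter):
        iterations = k + 1
        g = grad(y)
        f_y = smooth(y)
        # backtracking: grow L until the smooth part is majorized at the prox point
        while True:
            p = prox(y - g / L, 1.0 / L)
            d = p - y
            quad = f_y + float(np.vdot(g, d)) + 0.5 * L * float(np.vdot(d, d))
            if smooth(p) <= quad + 1e-12 * (1.0 + abs(f_y)):
                break
            L *= eta

        x_prev, x = x, p
        t_next = momentum_update(t)
        y = x + ((t - 1.0) / t_next) * (x - x_prev)
        t = t_next

        obj_new = smooth(x) + penalty(x)
        trace.append(obj_new)
        if abs(obj_new - obj) <= tol * max(1.0, abs(obj_new)):
            converged = True
            obj = obj_new
            break
        obj = obj_new

    return FistaResult(
        x=x,
        objective_trace=np.asarray(trace),
        lipschitz=L,
        converged=converged,
        iterations=iterations,
    )
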