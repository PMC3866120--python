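"""Cross-validation, lambda grids, RMSE reporting.

The tuning protocol mirrors the standard compendium benchmark: samples
are split into ten nonoverlapping folds; for each held-out fold the
regularization parameter is tuned by an inner ten-fold cross-validation
on the remaining nine (over a ten-point logarithmically spaced grid),
the model is refit at the selected lambda on all nine, and RMSE is
measured on the held-out fold.  Reported errors are the per-target
root-mean-square prediction error averaged over targets, summarized as
mean +/- sd over the outer folds.

Standardization (each gene to mean 0, variance 1) is fit on training
samples and applied to test samples by default; ``paper_mode=True``
instead rescales the full dataset once before splitting, the common
global-preprocessing variant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSpec, gram_matrix, resolve_bandwidth
from .kernel_model import fit_kernel_lowrank, predict_kernel
from .lasso import fit_lasso
from .linear import estimate_rank, fit_linear_lowrank, predict_linear

__all__ = [
    "MODEL_KINDS",
    "Standardizer",
    "FoldPlan",
    "make_fold_plan",
    "rmse",
    "make_lambda_grid",
    "fit_path",
    "tune_lambda",
    "TuneResult",
    "CVReport",
    "cross_validate",
]

MODEL_KINDS = ("linear_lowrank", "kernel_lowrank", "lasso")


class Standardizer:
    """Per-column (per-gene) centering and unit-variance scaling.

    Fit on training samples only; constant columns get unit scale so
    they map to zeros instead of dividing by zero.
    """

    def __init__(self):
        self.means_ = None
        self.stds_ = None

    def fit(self, M) -> "Standardizer":
        M = np.asarray(M, dtype=float)
        self.means_ = M.mean(axis=0)
        stds = M.std(axis=0, ddof=0)
        self.stds_ = np.where(stds > 1e-12, stds, 1.0)
        return self

    def transform(self, M) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("Standardizer is not fitted")
        return (np.asarray(M, dtype=float) - self.means_) / self.stds_

    def fit_transform(self, M) -> np.ndarray:
        return self.fit(M).transform(M)


@dataclass(frozen=True)
class FoldPlan:
    """Deterministic assignment of samples to cross-validation folds."""

    n_folds: int
    assignments: np.ndarray  # fold id per sample
    seed: int

    def __post_init__(self):
        counts = np.bincount(self.assignments, minlength=self.n_folds)
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes must differ by at most one")

    def split(self):
        """Yield (train_idx, test_idx) pairs per fold."""
        idx = np.arange(self.assignments.size)
        for f in range(self.n_folds):
            mask = self.assignments == f
            yield idx[~mask], idx[mask]


def make_fold_plan(n_samples: int, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Random balanced fold assignment, reproducible from the seed."""
    if n_folds < 2 or n_folds > n_samples:
        raise ValueError(
            f"n_folds must be in [2, n_samples]; got {n_folds} for {n_samples} samples"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    assignments = np.empty(n_samples, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds)):
        assignments[chunk] = f
    return FoldPlan(n_folds=n_folds, assignments=assignments, seed=seed)


def rmse(predicted, observed):
    """Per-target RMSE vector and its mean over targets."""
    P = np.asarray(predicted, dtype=float)
    O = np.asarray(observed, dtype=float)
    if P.shape != O.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {O.shape}")
    per_target = np.sqrt(np.mean((P - O) ** 2, axis=0))
    return per_target, float(per_target.mean())


def make_lambda_grid(
    X,
    Y,
    n_points: int = 10,
    span_decades: float = 4.0,
    kind: str = "lowrank",
) -> np.ndarray:
    """Log-spaced grid anchored at the exact zero-solution threshold.

    kind="lowrank": lambda_max = sigma_max(X^T Y), the smallest lambda
    at which W = 0 is optimal for the nuclear-norm problem.
    kind="lasso": lambda_max = max |X^T Y|, its entrywise analogue.
    The grid spans ``span_decades`` decades below lambda_max.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if span_decades <= 0:
        raise ValueError("span_decades must be positive")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    C = X.T @ Y
    if not np.any(C):
        raise ValueError("X^T Y is identically zero; no meaningful grid exists")
    if kind == "lowrank":
        lam_max = float(np.linalg.svd(C, compute_uv=False)[0])
    elif kind == "lasso":
        lam_max = float(np.abs(C).max())
    else:
        raise ValueError(f"unknown grid kind {kind!r}")
    return np.logspace(np.log10(lam_max) - span_decades, np.log10(lam_max), n_points)


def _grid_kind(model_kind: str) -> str:
    return "lasso" if model_kind == "lasso" else "lowrank"


def fit_path(
    model_kind: str,
    X,
    Y,
    grid,
    kernel_spec: KernelSpec | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
):
    """Fit one model per grid lambda, warm-starting from larger lambda.

    Returns fits in grid (ascending-lambda) order.  For the kernel
    model X is the raw regulator matrix; the Gram matrix is built here.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    grid = np.asarray(grid, dtype=float)
    order = np.argsort(grid)[::-1]  # largest lambda first: zero is exact there
    fits: list = [None] * grid.size
    warm = None
    if model_kind == "kernel_lowrank":
        spec = resolve_bandwidth(kernel_spec or KernelSpec("linear"), X)
        K = gram_matrix(spec, X)
        for i in order:
            fit = fit_kernel_lowrank(K, Y, grid[i], tol=tol, max_iter=max_iter, B0=warm)
            warm = fit.reparameterized_solution
            fits[i] = (fit, spec)
        return fits
    for i in order:
        if model_kind == "linear_lowrank":
            fit = fit_linear_lowrank(X, Y, grid[i], tol=tol, max_iter=max_iter, W0=warm)
        else:
            fit = fit_lasso(X, Y, grid[i], tol=tol, max_iter=max_iter, W0=warm)
        warm = fit.coefficients
        fits[i] = fit
    return fits


def _predict_fit(model_kind, fit, X_train, X_new):
    if model_kind == "kernel_lowrank":
        kfit, spec = fit
        return predict_kernel(kfit, spec, X_train, X_new)
    return fit.predict(X_new)


def _select_lambda(grid, mean_rmse) -> int:
    """Index of the best lambda; ties go to the larger (more regularized)."""
    best = mean_rmse.min()
    close = np.flatnonzero(mean_rmse <= best * (1.0 + 1e-12))
    return int(close.max())


@dataclass
class TuneResult:
    """Grid-search outcome of one K-fold cross-validation."""

    lambda_grid: np.ndarray
    per_fold_rmse: np.ndarray  # folds x grid
    mean_rmse: np.ndarray
    selected_index: int

    @property
    def selected_lambda(self) -> float:
        return float(self.lambda_grid[self.selected_index])


def tune_lambda(
    model_kind: str,
    X,
    Y,
    plan: FoldPlan | None = None,
    grid=None,
    n_folds: int = 10,
    seed: int = 0,
    kernel_spec: KernelSpec | None = None,
    standardize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 2000,
    grid_points: int = 10,
    span_decades: float = 4.0,
) -> TuneResult:
    """K-fold cross-validated grid search for lambda.

    Standardization (when enabled) is fit on each fold's training part
    and applied to its test part, so no test information leaks into the
    scaling.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if plan is None:
        plan = make_fold_plan(X.shape[0], n_folds=n_folds, seed=seed)
    if plan.assignments.size != X.shape[0]:
        raise ValueError("fold plan does not cover the dataset's samples")
    if grid is None:
        grid = make_lambda_grid(
            X, Y, n_points=grid_points, span_decades=span_decades, kind=_grid_kind(model_kind)
        )
    grid = np.asarray(grid, dtype=float)
    per_fold = np.empty((plan.n_folds, grid.size))
    for f, (tr, te) in enumerate(plan.split()):
        if te.size < 1 or tr.size < 2:
            raise ValueError(f"fold {f} is too small to train on")
        Xtr, Xte, Ytr, Yte = X[tr], X[te], Y[tr], Y[te]
        if standardize:
            sx, sy = Standardizer().fit(Xtr), Standardizer().fit(Ytr)
            Xtr, Xte = sx.transform(Xtr), sx.transform(Xte)
            Ytr, Yte = sy.transform(Ytr), sy.transform(Yte)
        fits = fit_path(model_kind, Xtr, Ytr, grid, kernel_spec, tol=tol, max_iter=max_iter)
        for i, fit in enumerate(fits):
            _, per_fold[f, i] = rmse(_predict_fit(model_kind, fit, Xtr, Xte), Yte)
    mean_rmse = per_fold.mean(axis=0)
    return TuneResult(
        lambda_grid=grid,
        per_fold_rmse=per_fold,
        mean_rmse=mean_rmse,
        selected_index=_select_lambda(grid, mean_rmse),
    )


@dataclass
class CVReport:
    """Nested cross-validation report.

    per_fold_rmse holds, for each outer fold, the inner-CV mean RMSE
    curve over the lambda grid.  selected_lambdas holds the per-outer-
    fold choices; ``selected_lambda`` summarizes them by the median.
    """

    model_kind: str
    lambda_grid: np.ndarray
    per_fold_rmse: np.ndarray  # outer folds x grid (inner mean curves)
    selected_lambdas: np.ndarray
    train_rmse: np.ndarray  # per outer fold, mean over targets
    test_rmse: np.ndarray
    per_target_test_rmse: np.ndarray  # pooled over held-out samples
    estimated_ranks: np.ndarray
    seed: int
    n_samples: int = 0
    n_targets: int = 0

    @property
    def selected_lambda(self) -> float:
        return float(np.median(self.selected_lambdas))

    @property
    def train_rmse_mean_sd(self):
        return float(self.train_rmse.mean()), float(self.train_rmse.std(ddof=1))

    @property
    def test_rmse_mean_sd(self):
        return float(self.test_rmse.mean()), float(self.test_rmse.std(ddof=1))

    @property
    def estimated_rank_at_selected(self) -> int:
        return int(np.median(self.estimated_ranks))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        tr_m, tr_s = self.train_rmse_mean_sd
        te_m, te_s = self.test_rmse_mean_sd
        d["summary"] = {
            "selected_lambda": self.selected_lambda,
            "train_rmse_mean": tr_m,
            "train_rmse_sd": tr_s,
            "test_rmse_mean": te_m,
            "test_rmse_sd": te_s,
            "estimated_rank": self.estimated_rank_at_selected,
        }
        return d

    def to_json(self, path) -> None:
        from .io import atomic_write_text

        atomic_write_text(path, json.dumps(self.to_dict(), indent=2))


def cross_validate(
    model_kind: str,
    X,
    Y,
    plan: FoldPlan | None = None,
    grid=None,
    n_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
    kernel_spec: KernelSpec | None = None,
    standardize: bool = True,
    paper_mode: bool = False,
    tol: float = 1e-6,
    max_iter: int = 2000,
    grid_points: int = 10,
    span_decades: float = 4.0,
) -> CVReport:
    """Nested cross-validation: inner grid search, outer evaluation.

    For each outer fold, lambda is tuned by ``inner_folds``-fold CV on
    that fold's training samples only (inner fold plans are derived
    deterministically from the outer seed), the model is refit at the
    selected lambda on all training samples, and train/test RMSE are
    recorded.  ``paper_mode`` standardizes the whole dataset once up
    front instead of within each fold.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, L_targets = Y.shape
    if plan is None:
        plan = make_fold_plan(n, n_folds=n_folds, seed=seed)
    if plan.assignments.size != n:
        raise ValueError("fold plan does not cover the dataset's samples")
    counts = np.bincount(plan.assignments, minlength=plan.n_folds)
    if counts.min() < 1 or (n - counts.max()) < 2:
        raise ValueError("each fold needs >= 1 test and >= 2 training samples")

    if paper_mode and standardize:
        X = Standardizer().fit_transform(X)
        Y = Standardizer().fit_transform(Y)
    fold_standardize = standardize and not paper_mode

    if grid is None:
        Xg = X if paper_mode or not standardize else Standardizer().fit_transform(X)
        Yg = Y if paper_mode or not standardize else Standardizer().fit_transform(Y)
        grid = make_lambda_grid(
            Xg, Yg, n_points=grid_points, span_decades=span_decades, kind=_grid_kind(model_kind)
        )
    grid = np.asarray(grid, dtype=float)

    inner_curves = np.empty((plan.n_folds, grid.size))
    selected = np.empty(plan.n_folds)
    train_scores = np.empty(plan.n_folds)
    test_scores = np.empty(plan.n_folds)
    ranks = np.empty(plan.n_folds, dtype=int)
    sq_err_sum = np.zeros(L_targets)
    held_out = 0

    for f, (tr, te) in enumerate(plan.split()):
        Xtr, Xte, Ytr, Yte = X[tr], X[te], Y[tr], Y[te]
        inner_plan = make_fold_plan(
            tr.size, n_folds=min(inner_folds, tr.size), seed=seed * 1000 + f + 1
        )
        tune = tune_lambda(
            model_kind,
            Xtr,
            Ytr,
            plan=inner_plan,
            grid=grid,
            kernel_spec=kernel_spec,
            standardize=fold_standardize,
            tol=tol,
            max_iter=max_iter,
        )
        inner_curves[f] = tune.mean_rmse
        lam = tune.selected_lambda
        selected[f] = lam

        if fold_standardize:
            sx, sy = Standardizer().fit(Xtr), Standardizer().fit(Ytr)
            Xtr, Xte = sx.transform(Xtr), sx.transform(Xte)
            Ytr, Yte = sy.transform(Ytr), sy.transform(Yte)
        fits = fit_path(model_kind, Xtr, Ytr, np.array([lam]), kernel_spec, tol=tol, max_iter=max_iter)
        fit = fits[0]
        pred_tr = _predict_fit(model_kind, fit, Xtr, Xtr)
        pred_te = _predict_fit(model_kind, fit, Xtr, Xte)
        _, train_scores[f] = rmse(pred_tr, Ytr)
        per_t, test_scores[f] = rmse(pred_te, Yte)
        sq_err_sum += per_t**2 * te.size
        held_out += te.size
        if model_kind == "kernel_lowrank":
            ranks[f] = fit[0].estimated_rank
        elif model_kind == "linear_lowrank":
            ranks[f] = fit.estimated_rank
        else:
            ranks[f] = estimate_rank(fit.coefficients) if np.any(fit.coefficients) else 0

    return CVReport(
        model_kind=model_kind,
        lambda_grid=grid,
        per_fold_rmse=inner_curves,
        selected_lambdas=selected,
        train_rmse=train_scores,
        test_rmse=test_scores,
        per_target_test_rmse=np.sqrt(sq_err_sum / held_out),
        estimated_ranks=ranks,
        seed=seed,
        n_samples=n,
        n_targets=L_targets,
    )
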