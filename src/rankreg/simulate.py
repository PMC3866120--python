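"""Synthetic expression data with planted low-rank regulatory structure.

The generator emulates the statistical shape the models assume: a panel
of p regulators measured in n samples (independent standard-normal
"standardized expression"), and L target genes driven through a
coefficient matrix of exact rank r — r independent regulatory modules
shared across targets — plus homoscedastic Gaussian measurement noise.
The kernel regime instead plants the targets' regulation functions in
an r-dimensional span of kernel sections at the samples.

Factor matrices are scaled so the noiseless per-target signal variance
is ~ coefficient_scale^2 regardless of p and r, keeping signal-to-noise
and lambda grids comparable across configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernels import KernelSpec, gram_matrix, psd_sqrt

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate_linear", "generate_kernel", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the benchmark regime used throughout the test
    suite: 150 samples, 40 regulators, 60 targets, 5 planted modules,
    noise sd 0.3 against unit signal variance.
    """

    n_samples: int = 150
    n_regulators: int = 40
    n_targets: int = 60
    rank: int = 5
    noise_sd: float = 0.3
    coefficient_scale: float = 1.0
    seed: int = 0
    regime: str = "linear"
    kernel: KernelSpec | None = None
    standardize: bool = False

    def __post_init__(self):
        if self.regime not in ("linear", "kernel"):
            raise ValueError(f"regime must be 'linear' or 'kernel', got {self.regime!r}")
        cap = min(self.n_regulators, self.n_targets) if self.regime == "linear" else min(
            self.n_samples, self.n_targets
        )
        if not (1 <= self.rank <= cap):
            raise ValueError(f"rank must lie in [1, {cap}] for this regime, got {self.rank}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if min(self.n_samples, self.n_regulators, self.n_targets) < 1:
            raise ValueError("all dimensions must be positive")


@dataclass
class SyntheticDataset:
    """Generated data plus the planted ground truth."""

    X: np.ndarray  # n x p regulators
    Y: np.ndarray  # n x L targets
    W_true: np.ndarray | None  # p x L (linear regime)
    A_true: np.ndarray | None  # n x L (kernel regime)
    module_loadings: tuple  # the rank-r factors
    noise: np.ndarray
    spec: SyntheticSpec


def _standardize_columns(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    return (M - mu) / sd


def generate_linear(spec: SyntheticSpec) -> SyntheticDataset:
    """X ~ N(0,1); W_true = scale * U V^T / sqrt(p r); Y = X W_true + noise."""
    if spec.regime != "linear":
        raise ValueError("generate_linear requires regime='linear'")
    rng = np.random.default_rng(spec.seed)
    n, p, L, r = spec.n_samples, spec.n_regulators, spec.n_targets, spec.rank
    X = rng.standard_normal((n, p))
    U = rng.standard_normal((p, r))
    V = rng.standard_normal((L, r))
    W = spec.coefficient_scale * (U @ V.T) / np.sqrt(p * r)
    E = spec.noise_sd * rng.standard_normal((n, L))
    Y = X @ W + E
    if spec.standardize:
        X = _standardize_columns(X)
        Y = _standardize_columns(Y)
    return SyntheticDataset(
        X=X, Y=Y, W_true=W, A_true=None, module_loadings=(U, V), noise=E, spec=spec
    )


def generate_kernel(spec: SyntheticSpec) -> SyntheticDataset:
    """Targets lie in a rank-r span of kernel sections at the samples.

    A_true = C M^T with C (n x r), M (L x r) Gaussian; the signal K
    A_true is rescaled so its empirical variance matches
    coefficient_scale^2, then noise is added.
    """
    if spec.regime != "kernel":
        raise ValueError("generate_kernel requires regime='kernel'")
    kspec = spec.kernel or KernelSpec("gaussian", bandwidth=None)
    rng = np.random.default_rng(spec.seed)
    n, p, L, r = spec.n_samples, spec.n_regulators, spec.n_targets, spec.rank
    X = rng.standard_normal((n, p))
    from .kernels import resolve_bandwidth

    kspec = resolve_bandwidth(kspec, X)
    K = gram_matrix(kspec, X)
    C = rng.standard_normal((n, r))
    M = rng.standard_normal((L, r))
    A = (C @ M.T) / np.sqrt(r)
    signal = K @ A
    s = signal.std()
    if s > 0:
        A = A * (spec.coefficient_scale / s)
        signal = signal * (spec.coefficient_scale / s)
    E = spec.noise_sd * rng.standard_normal((n, L))
    Y = signal + E
    if spec.standardize:
        X = _standardize_columns(X)
        Y = _standardize_columns(Y)
    return SyntheticDataset(
        X=X, Y=Y, W_true=None, A_true=A, module_loadings=(C, M), noise=E, spec=spec
    )


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Dispatch on the spec's regime."""
    return generate_linear(spec) if spec.regime == "linear" else generate_kernel(spec)
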