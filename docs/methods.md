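# Methods

## Models

**Linear low-rank model.** Samples are rows: `X` is `n × p` (regulator
expression), `Y` is `n × L` (target expression), both standardized per
gene to mean 0 and variance 1, so no intercept is needed. The fit is

    min_W  f(W) + λ‖W‖_*,   f(W) = ½‖Y − XW‖²_F,

with `∇f(W) = Xᵀ(XW − Y)`. The ½ scaling is a convention — any fixed
loss scaling is absorbed into λ — chosen so the gradient is clean and
the backtracking test matches the usual quadratic majorizer. Columns of
`W` are the per-target regulator weights; rank(`W`) is the number of
independent regulatory modules, and the nuclear norm is its tightest
convex surrogate.

**Kernel low-rank model.** Each target's regulation function `f_l`
lives in the RKHS of a Mercer kernel; the penalty is the sum of
singular values of the function system, equal to
`trace((AᵀKA)^{1/2}) = ‖K^{1/2}A‖_*` where `A` is the `n × L`
representer-coefficient matrix and `K` the training Gram matrix
(`function_gram` and the identity are exercised directly in the tests).
The solver works in `B = K^{1/2}A`:

    min_B  ½‖Y − K^{1/2}B‖²_F + λ‖B‖_*,    A = pinv(K^{1/2}) B.

`K^{1/2}` is the principal square root via eigendecomposition with
negative (numerical-noise) eigenvalues clipped at zero; its
pseudo-inverse treats eigenvalues below `1e-10·λ_max(K)` as exact
zeros, since Gram matrices are routinely rank-deficient. Gram matrices
failing PSD beyond `−1e-8·trace(K)` raise rather than being silently
repaired: that signals a misconfigured kernel.

**Lasso baseline.** Per-target `½‖y_l − Xw_l‖² + λ‖w_l‖₁`. The problem
is separable, so all targets are solved in one matrix-valued run of the
same engine with the entrywise soft-threshold prox — solutions are
identical to per-target fits, and using one engine keeps convergence
criteria uniform across the model comparison. λ is shared across
targets by default (tuned on mean CV RMSE, symmetric with the low-rank
model's single λ); a per-target λ vector is accepted.

## Solver

All three models use accelerated proximal gradient (FISTA) with
backtracking. Per iteration: find the smallest `L = η^i·L_{k−1}` such
that the smooth part satisfies `f(p) ≤ f(y) + ⟨∇f(y), p−y⟩ + (L/2)‖p−y‖²`
at the prox point `p = prox_{λ/L}(y − ∇f(y)/L)`; then momentum
`t_{k+1} = (1 + √(1+4t_k²))/2` and extrapolation
`y = x_k + ((t_k−1)/t_{k+1})(x_k − x_{k−1})`. Defaults `η = 2`,
`L₀ = 1`; correctness does not depend on them. The Lipschitz estimate
is non-decreasing within a fit. The prox of the nuclear norm is
singular-value soft-thresholding via thin SVD (cost dominated by the
SVD of a `p × L` or `n × L` matrix). Initialization is `W₀ = 0` (the
exact solution for `λ ≥ σ_max(XᵀY)`), warm starts are used along λ
paths (largest λ first, momentum reset). Convergence: relative
objective change ≤ 1e-8 within 5000 iterations by default (1e-6 / 2000
inside cross-validation, where selection only needs RMSE resolution far
coarser than that); hitting the cap flags the result not-converged
instead of raising.

**Rank reporting.** `estimate_rank` counts singular values above
`rel_tol·σ_max` with `rel_tol = 1e-8` — a scale-free spectral cutoff.
Note that the prediction-optimal λ typically retains a tail of small
noise singular values, so the reported rank at the CV-selected λ
upper-bounds the planted/true module count rather than matching it; λ
one or two grid steps larger usually reproduces the planted rank
exactly at a modest RMSE cost.

## Kernels

Families: linear `⟨x,z⟩`; Gaussian `exp(−‖x−z‖²/2h²)` with the median
pairwise-distance heuristic for `h` when unset; inhomogeneous
polynomial `(1+⟨x,z⟩)^d`; ANOVA of order `d` with per-coordinate
Gaussian base kernels, computed by the Newton–Girard recursion between
power sums and elementary symmetric polynomials (order 2 and unit
bandwidth by default — the natural per-coordinate scale on standardized
expression). The ANOVA order/base/bandwidth are exposed because no
single convention dominates; the brute-force subset enumeration backs
the recursion in tests.

## Cross-validation protocol

Ten outer folds (balanced, seeded); within each outer fold, λ is tuned
by inner ten-fold CV over a 10-point log-spaced grid, the model is
refit at the selected λ on all nine training subsets, and RMSE (per
target, then averaged over targets) is measured on the held-out fold.
Reported as mean ± sd over outer folds, with pooled per-target test
RMSE for model-vs-model scatter comparisons. The grid is anchored at
`λ_max = σ_max(XᵀY)` — the provable threshold above which `W = 0` is
optimal (`max|XᵀY|` for the Lasso) — and spans 4 decades down; an
absolute range would not transfer across datasets. Ties in mean CV
RMSE go to the larger λ (parsimony, deterministic). Standardization is
fit on training folds and applied to test folds (no leakage);
`paper_mode=True` instead rescales the full dataset once before
splitting, the common global-preprocessing variant, exposed so the
difference is explicit. Inner fold plans derive deterministically from
the outer seed, making every report bit-reproducible.

The benchmark protocol (`rankreg.benchmarks`) runs hold-out replicates:
per seed, an 80/20 train/test split, 10-fold CV tuning on the training
part, refit, held-out scoring. Problem sizes throughout (n=150, p=40,
L=60, r=5) keep a full replicate near one second so the whole benchmark
suite runs in minutes on one core.

## Synthetic data

The generator emulates the structure the models assume, not real
transcriptional dynamics: `X` i.i.d. standard normal ("standardized
expression"), `W_true = c·UVᵀ/√(pr)` with Gaussian factors — scaled so
the noiseless per-target signal variance is `c²` regardless of `p` and
`r`, keeping signal-to-noise and λ grids comparable across
configurations — and homoscedastic Gaussian noise (matching the
least-squares loss; heteroscedastic noise, gene-gene correlation
structure in `X`, outliers, and network dynamics are deliberately
absent, so passing tests certify the estimators and protocol, not
biological fidelity). Defaults: n=150, p=40, L=60, r=5, noise sd 0.3,
scale 1. The kernel regime plants `A_true = CMᵀ/√r` and rescales so the
signal `K·A_true` has unit variance empirically. Identical specs
reproduce identical arrays bit-for-bit.

## Numerical notes and limitations

- SVT and nuclear-norm evaluations use thin SVD; equal singular values
  need no tie-breaking since the reconstruction is unique.
- Comparing `‖K^{1/2}A‖_*` to `trace((AᵀKA)^{1/2})` in floating point
  is ill-posed for rank-deficient Grams: the eigenvalue route amplifies
  O(eps) noise to O(√eps) under the square root. Consumers of the
  identity should clip eigenvalues at machine-noise level first (the
  tests do).
- Constant (zero-variance) genes standardize to all-zeros rather than
  dividing by zero.
- FISTA is not monotone in the objective; the stopping rule uses the
  absolute relative change, which can in principle trigger during a
  momentum ripple — the certificate tests (subgradient optimality,
  reference-solver agreement) bound the practical effect well below
  the tolerances used.
- The combined sparse-plus-low-rank penalty, randomized/partial SVD,
  and kernel learning are out of scope.
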