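# rankreg

Low-rank regularized multi-target regression for learning gene
expression programs.

## The problem

Given expression measurements of a panel of `p` candidate regulators
(transcription factors, signalling molecules, or "landmark" genes) and
`L` target genes across `n` samples, we want the mapping from regulator
expression to target expression. Targets vastly outnumber samples and
measurements are noisy, so the regression must be regularized. Gene
regulation is *modular*: many targets share a small number of
regulatory programs, so the `p × L` coefficient matrix `W` in

    Y ≈ X W        (X: n × p regulators, Y: n × L targets, standardized)

should have low rank — its rank counts the independent regulator-to-
target connectivity patterns. `rankreg` fits

    min_W  ½‖Y − XW‖²_F + λ‖W‖_*

where `‖W‖_*` (the nuclear norm, the sum of singular values) is the
convex surrogate of rank. The same idea extends to nonlinear
regulation: each target's regulation function lives in the RKHS of a
Mercer kernel `k`, the functions are constrained to a shared
low-dimensional subspace, and by the representer theorem the problem
reduces to

    min_A  ½‖Y − KA‖²_F + λ‖K^{1/2}A‖_*

with `K` the training Gram matrix. Substituting `B = K^{1/2}A` gives a
plain nuclear-norm problem; both forms are solved by accelerated
proximal gradient (FISTA) with backtracking, using singular-value
soft-thresholding as the proximal step. A per-target Lasso baseline
(same engine, entrywise soft-threshold prox) and the ten-fold
cross-validation protocol for tuning λ over a 10-point log-spaced grid
complete the toolkit, together with a synthetic-data generator that
plants a known number of regulatory modules.

## Worked example

```python
from rankreg import SyntheticSpec, generate_linear, cross_validate

ds = generate_linear(SyntheticSpec(n_samples=100, n_regulators=20,
                                   n_targets=30, rank=4, seed=11))
for kind in ("linear_lowrank", "lasso"):
    rep = cross_validate(kind, ds.X, ds.Y, n_folds=5, inner_folds=5, seed=1)
    print(kind, rep.test_rmse_mean_sd)
```

Running `python examples/03_cross_validation.py` (which adds the
per-target comparison) prints:

```
linear_lowrank  train 0.3047 +/- 0.0075   test 0.3669 +/- 0.0134   lambda* 7.69
lasso           train 0.2941 +/- 0.0076   test 0.3886 +/- 0.0147   lambda* 0.471
targets predicted better by the low-rank model: 100%
estimated rank at selected lambda: 16
```

The data carry four planted modules under noise of sd 0.3 on
standardized (variance-1) targets, so a test RMSE near 0.37 means the
model explains most of the learnable signal; an unpredictable target
would score ~1.0. The Lasso fits each target separately and cannot
exploit the shared modules, hence its higher held-out error — the
low-rank model wins on every individual target here. The estimated
rank is the number of singular values the CV-tuned fit retains; it
upper-bounds the planted module count because prediction-optimal
shrinkage keeps some small noise directions.

Other examples: `examples/01_linear_lowrank.py` (single fit, rank and
objective), `examples/02_kernel_model.py` (Gaussian-kernel fit, the
function-space penalty identity, and the linear-kernel ≡ linear-model
equivalence), `examples/04_cli_pipeline.sh` (the shell pipeline).

## Command-line interface

```bash
rankreg simulate --seed 7 --out-prefix demo
rankreg fit --model linear-lowrank --expression demo_expression.tsv \
            --regulators demo_regulators.txt --lambda auto --out-prefix fit1
rankreg cv  --model lasso --expression demo_expression.tsv \
            --regulators demo_regulators.txt --out cv.json
rankreg report cv.json --per-target-out per_target.tsv
```

Expression matrices are TSV, genes as rows and samples as columns
(`--orientation` flips); regulator panels are plain text, one ID per
line. All writes are atomic and all numeric outputs are bit-reproducible
from `--seed`.

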