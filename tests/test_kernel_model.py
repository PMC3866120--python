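"""Kernelized low-rank model: objective identity, solver, prediction."""

import numpy as np
import pytest

from rankreg import (
    KernelSpec,
    fit_kernel_lowrank,
    fit_linear_lowrank,
    function_gram,
    gram_matrix,
    kernel_objective,
    linear_objective,
    nuclear_norm,
    predict_kernel,
    psd_sqrt,
)

from .oracles import ista_kernel_reference


def _kernel_problem(rng, n=20, p=4, L=5, rank=2, noise=0.1, family="gaussian"):
    X = rng.standard_normal((n, p))
    spec = KernelSpec(family, bandwidth=1.5)
    K = gram_matrix(spec, X)
    A = rng.standard_normal((n, rank)) @ rng.standard_normal((rank, L))
    signal = K @ A
    A = A / signal.std()
    Y = K @ A + noise * rng.standard_normal((n, L))
    return X, K, Y, spec


class TestObjective:
    def test_zero_coefficients(self, rng):
        _, K, Y, _ = _kernel_problem(rng)
        A0 = np.zeros((K.shape[0], Y.shape[1]))
        assert kernel_objective(A0, K, Y, 1.0) == pytest.approx(0.5 * np.sum(Y**2))

    def test_identity_kernel_reduces_to_linear(self, rng):
        Y = rng.standard_normal((8, 3))
        A = rng.standard_normal((8, 3))
        assert kernel_objective(A, np.eye(8), Y, 0.6) == pytest.approx(
            linear_objective(A, np.eye(8), Y, 0.6), abs=1e-10
        )

    def test_trace_identity_for_penalty(self, rng):
        # ||K^{1/2} A||_* == trace((A^T K A)^{1/2}): the function-space
        # penalty equals its finite reparameterized form
        _, K, Y, _ = _kernel_problem(rng)
        A = rng.standard_normal((K.shape[0], 4))
        lhs = nuclear_norm(psd_sqrt(K) @ A)
        G = function_gram(A, K)
        w = np.linalg.eigvalsh(G)
        w = np.where(w > w.max() * w.size * np.finfo(float).eps, w, 0.0)
        rhs = np.sqrt(w).sum()
        assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_shape_mismatch(self, rng):
        _, K, Y, _ = _kernel_problem(rng)
        with pytest.raises(ValueError):
            kernel_objective(np.zeros((3, 2)), K, Y, 1.0)


class TestFit:
    def test_zero_above_threshold(self, rng):
        X, K, Y, spec = _kernel_problem(rng)
        lam_max = np.linalg.svd(psd_sqrt(K) @ Y, compute_uv=False)[0]
        fit = fit_kernel_lowrank(K, Y, lam_max * 1.01)
        assert np.linalg.norm(fit.reparameterized_solution) <= 1e-10
        assert np.linalg.norm(fit.representer_coefficients) <= 1e-10
        assert np.all(predict_kernel(fit, spec, X, X) == 0)

    def test_identity_kernel_matches_linear_fit(self, rng):
        Y = rng.standard_normal((10, 4))
        kfit = fit_kernel_lowrank(np.eye(10), Y, 0.8, tol=1e-12)
        lfit = fit_linear_lowrank(np.eye(10), Y, 0.8, tol=1e-12)
        assert np.abs(kfit.representer_coefficients - lfit.coefficients).max() < 1e-8

    def test_matches_ista_reference(self, rng):
        _, K, Y, _ = _kernel_problem(rng, n=25, L=6)
        S = psd_sqrt(K)
        lam = 0.3 * np.linalg.svd(S @ Y, compute_uv=False)[0]
        fit = fit_kernel_lowrank(K, Y, lam, tol=1e-12, max_iter=50000)
        _, ref_obj = ista_kernel_reference(S, Y, lam)
        got = 0.5 * np.sum((Y - S @ fit.reparameterized_solution) ** 2) + lam * nuclear_norm(
            fit.reparameterized_solution
        )
        assert got <= ref_obj * (1 + 1e-6)

    def test_recovery_identity_A_from_B(self, rng):
        _, K, Y, _ = _kernel_problem(rng)
        fit = fit_kernel_lowrank(K, Y, 0.5)
        np.testing.assert_allclose(
            psd_sqrt(K) @ fit.representer_coefficients,
            fit.reparameterized_solution,
            atol=1e-6,
        )

    def test_rank_of_B_bounds_prediction_rank(self, rng):
        _, K, Y, _ = _kernel_problem(rng)
        fit = fit_kernel_lowrank(K, Y, 1.0)
        pred_rank = np.linalg.matrix_rank(K @ fit.representer_coefficients, tol=1e-8)
        assert fit.estimated_rank >= pred_rank


class TestPredict:
    def test_train_set_prediction_consistency(self, rng):
        X, K, Y, spec = _kernel_problem(rng)
        fit = fit_kernel_lowrank(K, Y, 0.5)
        np.testing.assert_allclose(
            predict_kernel(fit, spec, X, X), K @ fit.representer_coefficients, atol=1e-10
        )

    def test_linear_kernel_induces_linear_model(self, rng):
        # predictions equal X_new (X_train^T A): the induced p x L model
        rng2 = np.random.default_rng(7)
        X = rng2.standard_normal((15, 6))
        Y = rng2.standard_normal((15, 4))
        spec = KernelSpec("linear")
        K = gram_matrix(spec, X)
        fit = fit_kernel_lowrank(K, Y, 2.0, tol=1e-12)
        X_new = rng2.standard_normal((5, 6))
        W_induced = X.T @ fit.representer_coefficients
        np.testing.assert_allclose(
            predict_kernel(fit, spec, X, X_new), X_new @ W_induced, atol=1e-8
        )

    def test_dimension_mismatch(self, rng):
        X, K, Y, spec = _kernel_problem(rng)
        fit = fit_kernel_lowrank(K, Y, 0.5)
        with pytest.raises(ValueError):
            predict_kernel(fit, spec, X[:-1], X)


@pytest.mark.parametrize("shape", [(12, 20), (30, 8)])  # n < p and n > p
def test_linear_kernel_equivalence_with_linear_model(shape, rng):
    """Same lambda, linear kernel: the kernel fit reproduces the linear fit."""
    n, p = shape
    X = rng.standard_normal((n, p))
    W0 = rng.standard_normal((p, 5))
    Y = X @ W0 / np.sqrt(p) + 0.2 * rng.standard_normal((n, 5))
    lam = 0.3 * np.linalg.svd(X.T @ Y, compute_uv=False)[0]
    lfit = fit_linear_lowrank(X, Y, lam, tol=1e-12, max_iter=50000)
    spec = KernelSpec("linear")
    K = gram_matrix(spec, X)
    kfit = fit_kernel_lowrank(K, Y, lam, tol=1e-12, max_iter=50000)
    diff = predict_kernel(kfit, spec, X, X) - X @ lfit.coefficients
    assert np.sqrt(np.mean(diff**2)) < 1e-5
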