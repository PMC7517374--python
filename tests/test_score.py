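"""Score (gradient-log-density) estimators: kernels, fits, selection rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fpflow.score import (
    BasisFunction,
    KernelSpec,
    adaptive_length_scale,
    affine_basis,
    empirical_cost,
    estimate_score,
    fit_kernel,
    fit_linear,
    fit_score_model,
    fit_sparse,
    polynomial_basis_1d,
    rbf_eval,
    rbf_matrix,
    select_inducing,
)


class TestRBF:
    def test_coincident_points(self):
        spec = KernelSpec(length_scale=0.7)
        val, grad = rbf_eval(np.array([1.0, 2.0]), np.array([1.0, 2.0]), spec)
        assert val == pytest.approx(1.0)
        np.testing.assert_allclose(grad, 0.0)

    def test_unit_length_scale_separation(self):
        spec = KernelSpec(length_scale=0.4)
        val, _ = rbf_eval(np.array([0.4]), np.array([0.0]), spec)
        assert val == pytest.approx(np.exp(-0.5))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_gradient_matches_finite_difference(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 3))
        spec = KernelSpec(length_scale=float(rng.uniform(0.3, 2.0)))
        _, grad = rbf_eval(x, y, spec)
        h = 1e-6
        fd = np.array([
            (rbf_eval(x + h * e, y, spec)[0] - rbf_eval(x - h * e, y, spec)[0])
            / (2 * h)
            for e in np.eye(3)
        ])
        np.testing.assert_allclose(grad, fd, atol=1e-6)

    def test_symmetry_and_matrix_agreement(self, rng):
        spec = KernelSpec(length_scale=0.9)
        X = rng.normal(size=(6, 2))
        Z = rng.normal(size=(4, 2))
        K = rbf_matrix(X, Z, spec.length_scale)
        for i in range(6):
            for k in range(4):
                v, _ = rbf_eval(X[i], Z[k], spec)
                assert K[i, k] == pytest.approx(v)
                assert rbf_eval(Z[k], X[i], spec)[0] == pytest.approx(v)


class TestEmpiricalCost:
    @pytest.mark.parametrize(
        "phi,dphi,r,expected",
        [
            ([0.0, 0.0], [0.0, 0.0], [3.0, -1.0], 0.0),
            ([1.0, -1.0], [0.0, 0.0], [0.0, 0.0], 1.0),
            ([1.0], [0.0], [1.0], 3.0),
        ],
    )
    def test_values(self, phi, dphi, r, expected):
        assert empirical_cost(np.array(phi), np.array(dphi),
                              np.array(r)) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            empirical_cost(np.zeros(3), np.zeros(2), np.zeros(3))


class TestLinearFit:
    def test_standard_normal_score_exact(self, rng):
        """A sample with exact standard-normal first/second moments yields
        phi(x) = -x, i.e. coefficients (0, -1), exactly."""
        x = rng.normal(size=500)
        x = x - x.mean()
        x = x * np.sqrt(len(x) / np.sum(x**2))  # sum x = 0, sum x^2 = N
        a = fit_linear(x[:, None], polynomial_basis_1d(1), None, alpha=0)
        np.testing.assert_allclose(a, [0.0, -1.0], atol=1e-10)

    def test_reference_in_span_leaves_velocity_unchanged(self, rng):
        """When r lies in the basis span, the fitted velocity r + phi is
        invariant under replacing r by zero."""
        X = rng.normal(size=(120, 1))
        basis = polynomial_basis_1d(2)
        r = lambda Q: -3.0 * Q + 0.5  # affine, in span{1, x, x^2}
        a_r = fit_linear(X, basis, r, alpha=0)
        a_0 = fit_linear(X, basis, None, alpha=0)
        Q = np.linspace(-2, 2, 31)[:, None]
        Phi = np.column_stack([b.value(Q) for b in basis])
        vel_r = r(Q)[:, 0] + Phi @ a_r
        vel_0 = Phi @ a_0
        np.testing.assert_allclose(vel_r, vel_0, atol=1e-8)

    def test_too_few_samples_rejected(self, rng):
        X = rng.normal(size=(2, 1))
        with pytest.raises(ValueError, match="ridge"):
            fit_linear(X, polynomial_basis_1d(3), None, alpha=0)
        # ridge lifts the restriction
        a = fit_linear(X, polynomial_basis_1d(3), None, alpha=0, ridge=1e-3)
        assert np.all(np.isfinite(a))


class TestKernelFit:
    def test_huge_lambda_shrinks_to_zero(self, rng):
        X = rng.normal(size=(40, 1))
        a = fit_kernel(X, KernelSpec(length_scale=0.8), lam=1e12, r=None, alpha=0)
        assert np.max(np.abs(a)) < 1e-8

    def test_reference_invariance_at_small_lambda(self):
        """As lambda -> 0 the fitted velocity r + phi becomes independent of r."""
        # even design keeps the Gram matrix identifiable at tiny lambda
        X = np.linspace(-1.5, 1.5, 15)[:, None]
        spec = KernelSpec(length_scale=0.5)
        eq_ref = lambda Q: -2.0 * Q  # equilibrium score of N(0, 1/2)
        lam = 1e-8
        sm0 = fit_score_model(X, klass="kernel", spec=spec, lam=lam)
        smr = fit_score_model(X, klass="kernel", spec=spec, lam=lam,
                              reference=eq_ref)
        s0 = estimate_score(sm0, X)
        sr = estimate_score(smr, X)
        rel = np.linalg.norm(s0 - sr) / np.linalg.norm(s0)
        assert rel < 1e-3

    def test_monte_carlo_consistency_gaussian_score(self):
        """Score RMSE vs the exact N(0,1) score -x improves from N=100 to
        N=1000 (median over seeds)."""
        grid = np.linspace(-2, 2, 101)[:, None]
        spec = KernelSpec(length_scale=0.8)

        def rmse(N, seed):
            X = np.random.default_rng(seed).normal(size=(N, 1))
            sm = fit_score_model(X, klass="kernel", spec=spec, lam=1e-3)
            s = estimate_score(sm, grid)[:, 0]
            return np.sqrt(np.mean((s + grid[:, 0]) ** 2))

        seeds = range(5)
        small = np.median([rmse(100, s) for s in seeds])
        large = np.median([rmse(1000, s) for s in seeds])
        assert large < small


class TestSparseFit:
    def test_inducing_at_samples_matches_full_kernel(self):
        # well-separated points keep the Gram matrix well conditioned, so
        # the coefficient vectors (not just the fitted functions) agree
        X = np.array([-2.0, -1.2, -0.4, 0.4, 1.2, 2.0])[:, None]
        spec = KernelSpec(length_scale=0.4)
        lam = 1e-3
        a_full = fit_kernel(X, spec, lam, None, alpha=0)
        a_sparse = fit_sparse(X, X, spec, lam, eps=1e-12, r=None, alpha=0)
        np.testing.assert_allclose(a_sparse, a_full, atol=1e-6)

    def test_single_inducing_point_closed_form(self, rng):
        X = rng.normal(size=(30, 1))
        z = np.array([[0.2]])
        spec = KernelSpec(length_scale=0.7)
        eps = 1e-4
        a = fit_sparse(X, z, spec, lam=0.0, eps=eps, r=None, alpha=0)
        K = rbf_matrix(X, z, 0.7)[:, 0]
        dK = -(X[:, 0] - 0.2) / 0.7**2 * K
        expected = -np.sum(dK) / (np.sum(K**2) + eps)
        assert a[0] == pytest.approx(expected, rel=1e-10)

    def test_degenerate_penalties_reduce_to_linear_model(self, rng):
        """lambda, eps -> 0 turns the sparse family into the plain linear
        model with basis {K(., z_k)}."""
        X = rng.normal(size=(80, 1))
        Z = np.linspace(-1.5, 1.5, 5)[:, None]
        spec = KernelSpec(length_scale=0.9)
        a_sparse = fit_sparse(X, Z, spec, lam=0.0, eps=1e-12, r=None, alpha=0)

        def kernel_basis(z):
            z = z.copy()

            def value(Q, z=z):
                return rbf_matrix(Q, z[None, :], 0.9)[:, 0]

            def grad(Q, z=z):
                K = rbf_matrix(Q, z[None, :], 0.9)
                return -(Q - z[None, :]) / 0.9**2 * K

            return BasisFunction(value=value, grad=grad)

        a_lin = fit_linear(X, [kernel_basis(z) for z in Z], None, alpha=0)
        np.testing.assert_allclose(a_sparse, a_lin, atol=1e-6)

    def test_consistency_on_gaussian_ise_decreases_with_n(self):
        """Median integrated squared error of the sparse score estimate vs
        the exact Gaussian score decreases along N in {100, 400, 1600}."""
        grid = np.linspace(-1.96, 1.96, 121)[:, None]  # central 95% mass

        def ise(N, seed):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(N, 1))
            Z = select_inducing(X, 50, "uniform_box", rng_seed=rng)
            sm = fit_score_model(X, klass="sparse", Z=Z, lam=1e-3, eps=1e-6,
                                 spec=KernelSpec(length_scale=0.8))
            s = estimate_score(sm, grid)[:, 0]
            return np.trapezoid((s + grid[:, 0]) ** 2, grid[:, 0])

        seeds = range(20)
        medians = [np.median([ise(N, s) for s in seeds]) for N in (100, 400, 1600)]
        assert medians[0] > medians[1] > medians[2]


class TestEstimateScore:
    def test_zero_model_gives_zero(self, rng):
        X = rng.normal(size=(10, 2))
        sm = fit_score_model(X, klass="linear")
        sm.coeffs = np.zeros_like(sm.coeffs)
        np.testing.assert_allclose(estimate_score(sm, X), 0.0)

    def test_linear_evaluation_contract(self):
        X = np.array([[0.0], [1.0], [-1.0], [0.5]])
        sm = fit_score_model(X, klass="linear", basis=polynomial_basis_1d(1))
        sm.coeffs = np.array([[0.0, -1.0]])
        assert estimate_score(sm, np.array([[0.5]]))[0, 0] == pytest.approx(-0.5)

    def test_kernel_train_cache_matches_fresh_evaluation(self, rng):
        X = rng.normal(size=(40, 2))
        sm = fit_score_model(X, klass="kernel", lam=1e-3)
        np.testing.assert_allclose(sm.train_score, estimate_score(sm, X),
                                   atol=1e-12)

    def test_dimension_mismatch(self, rng):
        sm = fit_score_model(rng.normal(size=(10, 2)), klass="linear")
        with pytest.raises(ValueError, match="dimension"):
            estimate_score(sm, np.zeros((3, 5)))


class TestAdaptiveLengthScale:
    def test_isotropic_convention(self, rng):
        x = rng.normal(size=400)
        x = (x - x.mean()) / x.std(ddof=1)
        X = np.column_stack([0.5 * x, 0.5 * x[::-1]])
        assert adaptive_length_scale(X) == pytest.approx(1.0)

    def test_degenerate_fallback(self):
        X = np.ones((10, 2))
        assert adaptive_length_scale(X) == pytest.approx(1e-3)

    def test_anisotropic_mean(self, rng):
        x = rng.normal(size=300)
        x = (x - x.mean()) / x.std(ddof=1)
        X = np.column_stack([0.2 * x, 0.6 * x])
        assert adaptive_length_scale(X) == pytest.approx(0.8)


class TestSelectInducing:
    def test_uniform_box_containment_and_seeding(self, rng):
        X = rng.uniform(size=(50, 2))
        lo, hi = X.min(axis=0), X.max(axis=0)
        Z1 = select_inducing(X, 20, "uniform_box", rng_seed=7)
        Z2 = select_inducing(X, 20, "uniform_box", rng_seed=7)
        Z3 = select_inducing(X, 20, "uniform_box", rng_seed=8)
        assert Z1.shape == (20, 2)
        assert np.all(Z1 >= lo) and np.all(Z1 <= hi)
        np.testing.assert_array_equal(Z1, Z2)
        assert not np.array_equal(Z1, Z3)

    def test_grid_1d(self):
        X = np.array([[-1.0], [1.0]])
        Z = select_inducing(X, 3, "grid")
        np.testing.assert_allclose(sorted(Z[:, 0]), [-1.0, 0.0, 1.0])

    def test_grid_nearest_feasible_lattice(self, rng):
        X = rng.uniform(size=(30, 2))
        Z = select_inducing(X, 7, "grid")  # 7 is not a 2-d lattice size
        assert Z.shape[0] <= 7 and Z.shape[0] >= 4
        assert np.all(Z >= X.min(axis=0) - 1e-12)
        assert np.all(Z <= X.max(axis=0) + 1e-12)
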