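"""Analytic references and distributional metrics.

Gaussian propagation for linear SDEs (the moment ODEs ``m' = A m``,
``C' = A C + C A^T + sigma^2 I``), the closed-form Gaussian KL divergence,
the empirical 1-Wasserstein distance, per-dimension cumulants, and the
generator-expectation diagnostic used to check that the particle flow
transports expectations correctly over infinitesimal times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
import scipy.linalg
import scipy.spatial.distance
import scipy.stats
from scipy.integrate import solve_ivp
from scipy.optimize import linear_sum_assignment

from .models import SDEModel

__all__ = [
    "GaussianState",
    "Observable",
    "propagate_linear_gaussian",
    "stationary_gaussian",
    "gaussian_kl",
    "wasserstein1",
    "cumulants",
    "generator_expectation",
    "expectation_series",
    "empirical_time_derivative",
]

Array = np.ndarray


@dataclass
class GaussianState:
    """Mean and covariance of a linear-SDE solution at one time."""

    mean: Array
    cov: Array
    time: float = 0.0

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        w = np.linalg.eigvalsh(self.cov)
        if np.any(w < -1e-10):
            raise ValueError(f"covariance has negative eigenvalue {w.min():g}")

    @property
    def dimension(self) -> int:
        return self.mean.size


def propagate_linear_gaussian(A: Array, sigma: float, g0: GaussianState,
                              dt: float, T: float) -> list[GaussianState]:
    """Mean/covariance trajectory of ``dX = A X dt + sigma dB`` from ``g0``.

    Integrates the moment ODEs with an adaptive solver at tolerance 1e-10
    and returns states on the grid ``t = 0, dt, 2 dt, ..., ~T``.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    eig = np.linalg.eigvals(A)
    if np.any(eig.real >= 0):
        raise ValueError("drift matrix must be stable (eigenvalues in the left half-plane)")
    d = A.shape[0]
    if g0.dimension != d:
        raise ValueError("initial state dimension does not match A")
    t_eval = np.arange(0.0, T + 0.5 * dt, dt)
    y0 = np.concatenate([g0.mean, g0.cov.ravel()])

    def rhs(t: float, y: Array) -> Array:
        m = y[:d]
        C = y[d:].reshape(d, d)
        dm = A @ m
        dC = A @ C + C @ A.T + sigma**2 * np.eye(d)
        return np.concatenate([dm, dC.ravel()])

    sol = solve_ivp(rhs, (0.0, t_eval[-1]), y0, t_eval=t_eval,
                    rtol=1e-10, atol=1e-12, method="RK45")
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"moment ODE integration failed: {sol.message}")
    out = []
    for ti, yi in zip(sol.t, sol.y.T):
        C = yi[d:].reshape(d, d)
        out.append(GaussianState(mean=yi[:d], cov=0.5 * (C + C.T),
                                 time=float(ti + g0.time)))
    return out


def stationary_gaussian(A: Array, sigma: float) -> GaussianState:
    """Stationary state: the Lyapunov solution of ``A C + C A^T + sigma^2 I = 0``."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    d = A.shape[0]
    C = scipy.linalg.solve_continuous_lyapunov(A, -sigma**2 * np.eye(d))
    return GaussianState(mean=np.zeros(d), cov=0.5 * (C + C.T), time=np.inf)


def gaussian_kl(g1: GaussianState, g2: GaussianState) -> float:
    """``D(N1 || N2)`` in closed form; requires ``C2`` positive definite."""
    d = g1.dimension
    if g2.dimension != d:
        raise ValueError("dimension mismatch")
    try:
        c2 = scipy.linalg.cho_factor(g2.cov, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("second covariance must be positive definite") from exc
    tr = float(np.trace(scipy.linalg.cho_solve(c2, g1.cov)))
    dm = g2.mean - g1.mean
    quad = float(dm @ scipy.linalg.cho_solve(c2, dm))
    sign1, logdet1 = np.linalg.slogdet(g1.cov)
    logdet2 = 2.0 * float(np.sum(np.log(np.diagonal(c2[0]))))
    if sign1 <= 0:
        raise np.linalg.LinAlgError("first covariance must be positive definite")
    return 0.5 * (tr + quad - d + logdet2 - logdet1)


def wasserstein1(A: Array, B: Array, rng_seed: int = 0,
                 max_points: int = 2000) -> float:
    """Empirical 1-Wasserstein distance with Euclidean ground cost.

    1-D samples use the exact sorted-quantile coupling.  In higher
    dimension the exact linear-assignment transport is solved on at most
    ``max_points`` points per side; larger inputs are subsampled uniformly
    at random (seeded) to the smaller common size, so the value is
    deterministic given the seed.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("empty sample")
    if A.shape[1] != B.shape[1]:
        raise ValueError("samples must share the same dimension")
    if A.shape[1] == 1:
        return float(scipy.stats.wasserstein_distance(A[:, 0], B[:, 0]))
    k = min(A.shape[0], B.shape[0], max_points)
    rng = np.random.default_rng(rng_seed)
    if A.shape[0] > k:
        A = A[rng.choice(A.shape[0], size=k, replace=False)]
    if B.shape[0] > k:
        B = B[rng.choice(B.shape[0], size=k, replace=False)]
    cost = scipy.spatial.distance.cdist(A, B)
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean())


def cumulants(X: Array) -> Array:
    """Per-dimension (mean, std, skewness, excess kurtosis), shape ``(d, 4)``.

    Skewness and kurtosis are standardised central moments; kurtosis is
    reported as *excess* (a normal distribution gives 0).  For fewer than
    four samples, or a degenerate (zero-variance) dimension, the
    standardised moments are reported as NaN.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    out = np.empty((d, 4))
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1) if n > 1 else np.zeros(d)
    out[:, 0] = mean
    out[:, 1] = std
    for k in range(d):
        if n < 4 or std[k] == 0.0:
            out[k, 2] = np.nan
            out[k, 3] = np.nan
        else:
            out[k, 2] = scipy.stats.skew(X[:, k], bias=True)
            out[k, 3] = scipy.stats.kurtosis(X[:, k], fisher=True, bias=True)
    return out


class Observable(NamedTuple):
    """A scalar observable with analytic derivatives.

    ``value(X) -> (n,)``, ``grad(X) -> (n, d)``, ``laplacian(X) -> (n,)``
    for an ``(n, d)`` input.
    """

    value: Callable[[Array], Array]
    grad: Callable[[Array], Array]
    laplacian: Callable[[Array], Array]


def generator_expectation(model: SDEModel, X: Array, h: Observable) -> float:
    """Empirical ``<L h> = (1/N) sum_i [f(X_i) . grad h(X_i) + (sigma^2/2) lap h(X_i)]``.

    ``L`` is the generator of the diffusion; by the Fokker-Planck equation
    this equals ``d<h>/dt`` exactly under the true flow.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    F = model.drift_at(X)
    drift_term = np.sum(F * h.grad(X), axis=1)
    diff_term = 0.5 * model.noise_amplitude**2 * h.laplacian(X)
    return float(np.mean(drift_term + diff_term))


def expectation_series(times: Array, snapshots: list, h: Observable) -> Array:
    """``<h>`` under the empirical measure at each recorded time."""
    return np.array([float(np.mean(h.value(S))) for S in snapshots])


def empirical_time_derivative(times: Array, values: Array) -> Array:
    """Central-difference time derivative on a (possibly uneven) grid."""
    return np.gradient(np.asarray(values, dtype=float),
                       np.asarray(times, dtype=float))
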