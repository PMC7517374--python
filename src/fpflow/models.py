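"""Stochastic-dynamics model definitions and benchmark systems.

A model bundles everything a Fokker-Planck particle solver needs to know
about the underlying Ito SDE ``dX = f(X) dt + S(X) dB`` with
``S(x) S(x)^T = D(x)``:

* the drift ``f`` and its divergence (needed by the entropy-rate estimator),
* the diffusion matrix ``D`` (constant-isotropic ``sigma^2 I`` by default)
  and its divergence (the drift correction for multiplicative noise),
* optionally a potential ``U`` with ``f = -grad U``, in which case the
  stationary density is the Gibbs density and the equilibrium score
  ``grad ln p_inf = (2/sigma^2) f`` is available in closed form.

Second-order (underdamped) Langevin systems carry positions and velocities,
a dissipation constant ``gamma`` and the Hamiltonian ``H = |v|^2/2 + U(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "SDEModel",
    "LangevinModel",
    "benchmark_model",
    "matrix_sqrt_diffusion",
    "finite_difference_divergence",
]

Array = np.ndarray


def _fd_step(x: Array) -> float:
    return 1e-5 * (1.0 + float(np.max(np.abs(x))))


def finite_difference_divergence(func: Callable[[Array], Array], x: Array) -> float:
    """Central finite-difference divergence of a vector field at one state."""
    x = np.asarray(x, dtype=float)
    h = _fd_step(x)
    div = 0.0
    for a in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[a] += h
        xm[a] -= h
        div += (func(xp)[a] - func(xm)[a]) / (2.0 * h)
    return div


@dataclass
class SDEModel:
    """First-order SDE ``dX = f(X) dt + S(X) dB`` with ``S S^T = D``.

    Parameters
    ----------
    dimension : int
        State dimension ``d``.
    drift : callable
        ``f(x) -> (d,)`` evaluated at a single state.
    noise_amplitude : float
        ``sigma > 0``; used when the diffusion is constant-isotropic
        ``D = sigma^2 I`` (the default when ``diffusion`` is None).
    diffusion : callable, optional
        ``D(x) -> (d, d)`` symmetric PSD matrix; None means ``sigma^2 I``.
    diffusion_divergence : callable, optional
        ``(div D)(x) -> (d,)`` with component ``a = sum_b d_b D[a, b]``.
        Defaults to zero for constant diffusion.
    drift_divergence : callable, optional
        ``(div f)(x) -> float``; falls back to central finite differences.
    potential : callable, optional
        ``U(x) -> float`` with ``f = -grad U`` (equilibrium systems only).
    equilibrium_score : callable, optional
        ``grad ln p_inf(x) -> (d,)``; for equilibrium systems this equals
        ``(2/sigma^2) f(x)``.
    """

    dimension: int
    drift: Callable[[Array], Array]
    noise_amplitude: float = 1.0
    diffusion: Optional[Callable[[Array], Array]] = None
    diffusion_divergence: Optional[Callable[[Array], Array]] = None
    drift_divergence: Optional[Callable[[Array], float]] = None
    potential: Optional[Callable[[Array], float]] = None
    equilibrium_score: Optional[Callable[[Array], Array]] = None
    name: str = "custom"
    # optional vectorised fast paths over an (N, d) ensemble; the scalar
    # callables above remain the source of truth and the fallback
    drift_vec: Optional[Callable[[Array], Array]] = None
    drift_div_vec: Optional[Callable[[Array], Array]] = None
    diffusion_div_vec: Optional[Callable[[Array], Array]] = None
    diffusion_matvec: Optional[Callable[[Array, Array], Array]] = None
    diffusion_sqrt_matvec: Optional[Callable[[Array, Array], Array]] = None

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be a positive integer")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be non-negative")
        if self.potential is not None and self.equilibrium_score is None:
            if self.noise_amplitude > 0:
                s2 = self.noise_amplitude**2
                f = self.drift
                self.equilibrium_score = lambda x: (2.0 / s2) * np.asarray(f(x))

    # -- vectorised evaluation over an ensemble ---------------------------
    def drift_at(self, X: Array) -> Array:
        """Drift evaluated row-wise on an (N, d) ensemble."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.drift_vec is not None:
            return np.asarray(self.drift_vec(X), dtype=float)
        return np.array([np.asarray(self.drift(x), dtype=float) for x in X])

    def drift_divergence_ensemble(self, X: Array) -> Array:
        """``div f`` evaluated row-wise, ``(N,)``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.drift_div_vec is not None:
            return np.asarray(self.drift_div_vec(X), dtype=float)
        return np.array([self.drift_divergence_at(x) for x in X])

    def diffusion_divergence_ensemble(self, X: Array) -> Array:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.diffusion is None:
            return np.zeros_like(X)
        if self.diffusion_div_vec is not None:
            return np.asarray(self.diffusion_div_vec(X), dtype=float)
        return np.array([self.diffusion_divergence_at(x) for x in X])

    def diffusion_apply_ensemble(self, X: Array, S: Array) -> Array:
        """Row-wise matrix-vector products ``D(X_i) S_i``, ``(N, d)``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        S = np.atleast_2d(np.asarray(S, dtype=float))
        if self.diffusion is None:
            return self.noise_amplitude**2 * S
        if self.diffusion_matvec is not None:
            return np.asarray(self.diffusion_matvec(X, S), dtype=float)
        return np.array([self.diffusion_at(x) @ s for x, s in zip(X, S)])

    def diffusion_sqrt_apply_ensemble(self, X: Array, xi: Array) -> Array:
        """Row-wise ``S(X_i) xi_i`` with ``S S^T = D`` (noise realisation)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        xi = np.atleast_2d(np.asarray(xi, dtype=float))
        if self.diffusion is None:
            return self.noise_amplitude * xi
        if self.diffusion_sqrt_matvec is not None:
            return np.asarray(self.diffusion_sqrt_matvec(X, xi), dtype=float)
        return np.array([
            matrix_sqrt_diffusion(self, x) @ z for x, z in zip(X, xi)
        ])

    @property
    def is_constant_isotropic(self) -> bool:
        return self.diffusion is None

    @property
    def is_equilibrium(self) -> bool:
        return self.potential is not None

    def diffusion_at(self, x: Array) -> Array:
        if self.diffusion is None:
            return self.noise_amplitude**2 * np.eye(self.dimension)
        return np.asarray(self.diffusion(np.asarray(x, dtype=float)), dtype=float)

    def diffusion_divergence_at(self, x: Array) -> Array:
        if self.diffusion_divergence is not None:
            return np.asarray(self.diffusion_divergence(x), dtype=float)
        if self.diffusion is None:
            return np.zeros(self.dimension)
        # central finite differences on each column of D
        x = np.asarray(x, dtype=float)
        h = _fd_step(x)
        div = np.zeros(self.dimension)
        for b in range(self.dimension):
            xp, xm = x.copy(), x.copy()
            xp[b] += h
            xm[b] -= h
            div += (self.diffusion_at(xp)[:, b] - self.diffusion_at(xm)[:, b]) / (2 * h)
        return div

    def drift_divergence_at(self, x: Array) -> float:
        if self.drift_divergence is not None:
            return float(self.drift_divergence(np.asarray(x, dtype=float)))
        return finite_difference_divergence(self.drift, x)


@dataclass
class LangevinModel:
    """Underdamped Langevin system: ``dX = V dt``, ``dV = (-gamma V + f(X)) dt + sigma dB``.

    ``f = -grad U``; the stationary density is ``exp(-beta H)`` with
    ``beta = 2 gamma / sigma^2`` and ``H(x, v) = |v|^2 / 2 + U(x)``.
    """

    dimension: int
    potential: Callable[[Array], float]
    force: Callable[[Array], Array]
    dissipation: float = 1.0
    noise_amplitude: float = 1.0
    name: str = "langevin"
    force_vec: Optional[Callable[[Array], Array]] = None

    def __post_init__(self) -> None:
        if self.dissipation <= 0:
            raise ValueError("dissipation gamma must be positive")
        if self.noise_amplitude <= 0:
            raise ValueError("noise_amplitude sigma must be positive")

    @property
    def inverse_temperature(self) -> float:
        return 2.0 * self.dissipation / self.noise_amplitude**2

    def hamiltonian(self, x: Array, v: Array) -> float:
        v = np.asarray(v, dtype=float)
        return 0.5 * float(v @ v) + float(self.potential(np.asarray(x, dtype=float)))

    def force_at(self, X: Array) -> Array:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.force_vec is not None:
            return np.asarray(self.force_vec(X), dtype=float)
        return np.array([np.asarray(self.force(x), dtype=float) for x in X])

    def equilibrium_velocity_score(self, V: Array) -> Array:
        """``grad_v ln p_inf = -beta v`` (Maxwellian velocity marginal)."""
        return -self.inverse_temperature * np.asarray(V, dtype=float)


# ---------------------------------------------------------------------------
# benchmark constructors
# ---------------------------------------------------------------------------


def _ou(A: Optional[Array] = None, sigma: float = 1.0, dimension: int = 2) -> SDEModel:
    if A is None:
        A = -np.eye(dimension)
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("OU drift matrix A must be square")
    eig = np.linalg.eigvals(A)
    if np.any(eig.real >= 0):
        raise ValueError(
            f"OU drift matrix must be stable; eigenvalues with non-negative "
            f"real part found: {eig[eig.real >= 0]}"
        )
    d = A.shape[0]
    symmetric = np.allclose(A, A.T)
    potential = (lambda x, A=A: -0.5 * float(x @ A @ x)) if symmetric else None
    tr = float(np.trace(A))
    return SDEModel(
        dimension=d,
        drift=lambda x, A=A: A @ x,
        noise_amplitude=sigma,
        drift_divergence=lambda x, tr=tr: tr,
        potential=potential,
        name="ou",
        drift_vec=lambda X, A=A: X @ A.T,
        drift_div_vec=lambda X, tr=tr: np.full(X.shape[0], tr),
    )


def _double_well(sigma: float = 1.0) -> SDEModel:
    # U(x) = x^4 - 2 x^2, f = -U' = -4 x^3 + 4 x
    return SDEModel(
        dimension=1,
        drift=lambda x: -4.0 * x**3 + 4.0 * x,
        noise_amplitude=sigma,
        drift_divergence=lambda x: float(-12.0 * x[0] ** 2 + 4.0),
        potential=lambda x: float(x[0] ** 4 - 2.0 * x[0] ** 2),
        name="double_well",
        drift_vec=lambda X: -4.0 * X**3 + 4.0 * X,
        drift_div_vec=lambda X: -12.0 * X[:, 0] ** 2 + 4.0,
    )


def _multiplicative_bistable(sigma: float = 1.0,
                             drift: Optional[Callable[[Array], Array]] = None) -> SDEModel:
    # bistable drift with state-dependent diffusion D(x) = sin^2(x)
    f = drift if drift is not None else (lambda x: 4.0 * (x - x**3))
    return SDEModel(
        dimension=1,
        drift=f,
        noise_amplitude=sigma,
        diffusion=lambda x: np.array([[np.sin(x[0]) ** 2]]),
        diffusion_divergence=lambda x: np.array([np.sin(2.0 * x[0])]),
        drift_divergence=None if drift is not None
        else (lambda x: float(4.0 - 12.0 * x[0] ** 2)),
        name="multiplicative_bistable",
        drift_vec=None if drift is not None else (lambda X: 4.0 * (X - X**3)),
        diffusion_div_vec=lambda X: np.sin(2.0 * X),
        diffusion_matvec=lambda X, S: np.sin(X) ** 2 * S,
        diffusion_sqrt_matvec=lambda X, xi: np.abs(np.sin(X)) * xi,
    )


def _lorenz(sigma: float = 2.0, sigma_l: float = 10.0, rho: float = 28.0,
            beta_l: float = 8.0 / 3.0) -> SDEModel:
    def drift(x: Array) -> Array:
        return np.array([
            sigma_l * (x[1] - x[0]),
            x[0] * (rho - x[2]) - x[1],
            x[0] * x[1] - beta_l * x[2],
        ])

    def drift_vec(X: Array) -> Array:
        return np.column_stack([
            sigma_l * (X[:, 1] - X[:, 0]),
            X[:, 0] * (rho - X[:, 2]) - X[:, 1],
            X[:, 0] * X[:, 1] - beta_l * X[:, 2],
        ])

    const_div = -(sigma_l + 1.0 + beta_l)
    return SDEModel(
        dimension=3,
        drift=drift,
        noise_amplitude=sigma,
        drift_divergence=lambda x: const_div,
        name="lorenz",
        drift_vec=drift_vec,
        drift_div_vec=lambda X: np.full(X.shape[0], const_div),
    )


def _langevin(potential: Callable[[Array], float], force: Callable[[Array], Array],
              gamma: float, sigma: float, name: str,
              force_vec: Optional[Callable[[Array], Array]] = None) -> LangevinModel:
    return LangevinModel(dimension=1, potential=potential, force=force,
                         dissipation=gamma, noise_amplitude=sigma, name=name,
                         force_vec=force_vec)


_BENCHMARKS = {
    "ou": _ou,
    "double_well": _double_well,
    "multiplicative_bistable": _multiplicative_bistable,
    "lorenz": _lorenz,
    "langevin_harmonic": lambda gamma=1.0, sigma=1.0: _langevin(
        potential=lambda x: float(2.0 * x[0] ** 2),
        force=lambda x: -4.0 * x,
        gamma=gamma, sigma=sigma, name="langevin_harmonic",
        force_vec=lambda X: -4.0 * X),
    "langevin_double_well": lambda gamma=1.0, sigma=1.0: _langevin(
        potential=lambda x: float(x[0] ** 4 - 2.0 * x[0] ** 2),
        force=lambda x: -4.0 * x**3 + 4.0 * x,
        gamma=gamma, sigma=sigma, name="langevin_double_well",
        force_vec=lambda X: -4.0 * X**3 + 4.0 * X),
}


def benchmark_model(name: str, **params):
    """Construct one of the bundled benchmark systems.

    Names: ``ou`` (stable linear drift, default ``A = -I``), ``double_well``
    (``f = -4x^3 + 4x``), ``multiplicative_bistable`` (``f = 4(x - x^3)``,
    ``D(x) = sin^2 x``), ``lorenz`` (chaotic parameters, additive noise),
    ``langevin_harmonic`` (``f = -4x``) and ``langevin_double_well``.
    """
    try:
        ctor = _BENCHMARKS[name]
    except KeyError:
        raise ValueError(
            f"unknown benchmark {name!r}; available: {sorted(_BENCHMARKS)}"
        ) from None
    return ctor(**params)


def matrix_sqrt_diffusion(model: SDEModel, x: Array, tol: float = 1e-10) -> Array:
    """Principal square root ``S`` of ``D(x)`` with ``S S^T = D(x)``.

    Diagonal matrices use the elementwise root; general symmetric PSD
    matrices go through an eigendecomposition. A negative eigenvalue
    beyond ``tol`` (relative to the largest) is an error.
    """
    D = model.diffusion_at(x)
    if np.allclose(D, np.diag(np.diagonal(D))):
        diag = np.diagonal(D).copy()
        if np.any(diag < -tol * max(1.0, np.max(np.abs(diag)))):
            raise ValueError(f"diffusion matrix not PSD at state {np.asarray(x)}")
        return np.diag(np.sqrt(np.clip(diag, 0.0, None)))
    w, V = np.linalg.eigh(0.5 * (D + D.T))
    if np.any(w < -tol * max(1.0, float(np.max(np.abs(w))))):
        raise ValueError(
            f"diffusion matrix has negative eigenvalue {w.min():g} at state "
            f"{np.asarray(x)}"
        )
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
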