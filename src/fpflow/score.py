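"""Gradient-log-density (score) estimation from particle ensembles.

The score ``grad ln p(x)`` of an unknown density is characterised
variationally: component ``a`` equals ``r_a(x) + phi*(x)`` where ``phi*``
minimises the score-matching cost

    L_a[phi] = E_p[ phi^2 + 2 r_a phi + 2 d_a phi ],

an expectation free of the normalising constant (integration by parts
trades the unknown score for the derivative of the trial function).
Replacing ``p`` by the empirical measure of ``N`` particles gives a cost
that is quadratic in the coefficients of any linearly-parametrised trial
family, so the minimiser is a single symmetric linear solve.

Three families are implemented:

* ``linear`` — a fixed basis ``phi = sum_k a_k b_k(x)`` (exact for
  Gaussian densities with an affine basis);
* ``kernel`` — the full RKHS family ``phi = sum_i a_i K(x, X_i)`` with
  penalty ``(lambda/N) ||phi||_RKHS^2`` (an N x N solve);
* ``sparse`` — ``phi = sum_k a_k K(x, z_k)`` on ``M << N`` inducing
  points with penalty ``(lambda/N) ||phi||_RKHS^2 + (eps/N) ||a||^2``
  (an M x M solve; the workhorse inside the particle solver).

Each of the ``d`` score components is fitted independently; the solves
share one matrix factorisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "KernelSpec",
    "BasisFunction",
    "ScoreModel",
    "rbf_eval",
    "rbf_matrix",
    "rbf_grad",
    "empirical_cost",
    "fit_linear",
    "fit_kernel",
    "fit_sparse",
    "fit_score_model",
    "estimate_score",
    "adaptive_length_scale",
    "select_inducing",
    "affine_basis",
    "polynomial_basis_1d",
]

logger = logging.getLogger(__name__)

Array = np.ndarray

#: floor for the adaptive length scale when the ensemble is degenerate
MIN_LENGTH_SCALE = 1e-3


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian RBF kernel ``K(x, y) = exp(-|x - y|^2 / (2 l^2))``."""

    length_scale: float = 1.0
    family: str = "rbf"
    length_scale_mode: str = "fixed"  # "fixed" | "adaptive"

    def __post_init__(self) -> None:
        if self.family != "rbf":
            raise ValueError(f"unsupported kernel family {self.family!r}")
        if self.length_scale <= 0:
            raise ValueError("length_scale must be positive")


def rbf_eval(x: Array, y: Array, spec: KernelSpec) -> tuple[float, Array]:
    """Kernel value and its gradient with respect to ``x`` at one pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    l2 = spec.length_scale**2
    diff = x - y
    val = float(np.exp(-0.5 * (diff @ diff) / l2))
    return val, -diff / l2 * val


def rbf_matrix(X: Array, Z: Array, length_scale: float) -> Array:
    """Gram matrix ``K[i, k] = K(X_i, Z_k)`` (vectorised)."""
    X = np.atleast_2d(X)
    Z = np.atleast_2d(Z)
    sq = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Z**2, axis=1)[None, :]
        - 2.0 * X @ Z.T
    )
    return np.exp(-0.5 * np.clip(sq, 0.0, None) / length_scale**2)


def rbf_grad(X: Array, Z: Array, length_scale: float, alpha: int,
             K: Optional[Array] = None) -> Array:
    """``G[i, k] = d/dx^alpha K(x, Z_k) | x = X_i`` (derivative in the first slot)."""
    if K is None:
        K = rbf_matrix(X, Z, length_scale)
    diff = X[:, alpha][:, None] - Z[:, alpha][None, :]
    return -diff / length_scale**2 * K


def empirical_cost(phi_vals: Array, dphi_vals: Array, r_vals: Array) -> float:
    """Empirical score-matching cost ``(1/N) sum [phi^2 + 2 r phi + 2 d_a phi]``."""
    phi_vals = np.asarray(phi_vals, dtype=float)
    dphi_vals = np.asarray(dphi_vals, dtype=float)
    r_vals = np.asarray(r_vals, dtype=float)
    if not (phi_vals.shape == dphi_vals.shape == r_vals.shape) or phi_vals.ndim != 1:
        raise ValueError("phi, dphi and r value arrays must be 1-D of equal length")
    n = phi_vals.size
    if n < 1:
        raise ValueError("need at least one sample")
    return float(np.sum(phi_vals**2 + 2.0 * r_vals * phi_vals + 2.0 * dphi_vals) / n)


def _solve_kernel_system(K: Array, lam: float, B: Array,
                         rcond: float = 1e-12) -> Array:
    """Solve ``(K^2 + lam K) x = B`` through the eigendecomposition of ``K``.

    Kernel Gram matrices are numerically rank-deficient for clustered
    particles; forming ``K^2`` squares the condition number, so a direct
    factorisation loses genuine small-eigenvalue curvature.  Eigen-solving
    ``K`` and inverting ``mu^2 + lam mu`` per mode (modes below
    ``rcond * mu_max`` truncated — the objective is flat there) is the
    stable equivalent.
    """
    w, V = np.linalg.eigh(K)
    wmax = float(w.max()) if w.size else 1.0
    keep = w > rcond * max(wmax, 0.0)
    w = w[keep]
    V = V[:, keep]
    inv = 1.0 / (w**2 + lam * w)
    B2 = B if B.ndim == 2 else B[:, None]
    out = V @ (inv[:, None] * (V.T @ B2))
    return out if B.ndim == 2 else out[:, 0]


def _solve_spd(A: Array, B: Array, jitter: float) -> Array:
    """Solve the symmetric system ``A x = B`` by Cholesky with escalating jitter."""
    scale = float(np.mean(np.diagonal(A))) or 1.0
    for j in (0.0, jitter, 10.0 * jitter, 100.0 * jitter):
        try:
            c, low = scipy.linalg.cho_factor(
                A + j * scale * np.eye(A.shape[0]), lower=True, check_finite=False
            )
            return scipy.linalg.cho_solve((c, low), B, check_finite=False)
        except np.linalg.LinAlgError:
            continue
        except scipy.linalg.LinAlgError:  # pragma: no cover - alias on some scipy
            continue
    cond = np.linalg.cond(A)
    raise np.linalg.LinAlgError(
        f"symmetric system not factorizable after jitter escalation "
        f"(condition estimate {cond:.3e}); increase jitter or regularisation"
    )


# ---------------------------------------------------------------------------
# linear (fixed-basis) fits
# ---------------------------------------------------------------------------


class BasisFunction(NamedTuple):
    """A trial basis function with its analytic gradient.

    ``value(X) -> (n,)`` and ``grad(X) -> (n, d)`` for an ``(n, d)`` input.
    """

    value: Callable[[Array], Array]
    grad: Callable[[Array], Array]


def affine_basis(dimension: int) -> list[BasisFunction]:
    """Basis ``{1, x_1, ..., x_d}`` — exactly representing Gaussian scores."""
    funcs = [
        BasisFunction(
            value=lambda X: np.ones(X.shape[0]),
            grad=lambda X: np.zeros_like(X),
        )
    ]

    def _coord(k: int) -> BasisFunction:
        def grad(X: Array, k: int = k) -> Array:
            G = np.zeros_like(X)
            G[:, k] = 1.0
            return G

        return BasisFunction(value=lambda X, k=k: X[:, k].copy(), grad=grad)

    funcs.extend(_coord(k) for k in range(dimension))
    return funcs


def polynomial_basis_1d(degree: int) -> list[BasisFunction]:
    """Monomials ``{1, x, ..., x^degree}`` on a one-dimensional state."""

    def _mono(p: int) -> BasisFunction:
        def grad(X: Array, p: int = p) -> Array:
            if p == 0:
                return np.zeros_like(X)
            return p * X ** (p - 1)

        return BasisFunction(value=lambda X, p=p: X[:, 0] ** p, grad=grad)

    return [_mono(p) for p in range(degree + 1)]


def _zero_reference(X: Array) -> Array:
    return np.zeros_like(np.atleast_2d(X))


def fit_linear(X: Array, basis: Sequence[BasisFunction],
               r: Optional[Callable[[Array], Array]], alpha: int,
               ridge: float = 0.0) -> Array:
    """Minimise the empirical cost over ``span{b_1 .. b_m}`` for component ``alpha``.

    Returns ``a = -(C + ridge I)^{-1} b`` with ``C_kl = sum_i b_k(X_i) b_l(X_i)``
    and ``b_k = sum_i [d_alpha b_k(X_i) + b_k(X_i) r_alpha(X_i)]``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, m = X.shape[0], len(basis)
    if ridge == 0.0 and n < m + 1:
        raise ValueError(
            f"need N >= m+1 samples ({n} < {m + 1}); enable ridge > 0 or use "
            f"fewer basis functions"
        )
    r_fn = r if r is not None else _zero_reference
    r_a = np.atleast_2d(r_fn(X))[:, alpha]
    Phi = np.column_stack([b.value(X) for b in basis])  # (n, m)
    dPhi = np.column_stack([b.grad(X)[:, alpha] for b in basis])
    C = Phi.T @ Phi + ridge * np.eye(m)
    rhs = dPhi.sum(axis=0) + Phi.T @ r_a
    try:
        return -_solve_spd(C, rhs, jitter=0.0 if ridge else 1e-12)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular basis Gram matrix; enable ridge regularisation or use "
            "fewer basis functions"
        ) from exc


def fit_kernel(X: Array, spec: KernelSpec, lam: float,
               r: Optional[Callable[[Array], Array]], alpha: int,
               jitter: float = 1e-10) -> Array:
    """Full RKHS fit: solve ``(K^2 + lambda K) a = -(K r_a + G^T 1)``.

    ``K`` is the particle Gram matrix and ``G[l, k] = d_alpha K(x, X_k)|X_l``;
    the system is the stationarity condition of the empirical cost plus the
    RKHS penalty ``(lambda/N) ||phi||^2``.
    """
    if lam <= 0:
        raise ValueError("kernel fit requires lambda > 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("kernel fit needs at least two particles")
    r_fn = r if r is not None else _zero_reference
    r_a = np.atleast_2d(r_fn(X))[:, alpha]
    K = rbf_matrix(X, X, spec.length_scale)
    G = rbf_grad(X, X, spec.length_scale, alpha, K=K)
    rhs = K @ r_a + G.sum(axis=0)
    return -_solve_kernel_system(K, lam, rhs)


def fit_sparse(X: Array, Z: Array, spec: KernelSpec, lam: float, eps: float,
               r: Optional[Callable[[Array], Array]], alpha: int) -> Array:
    """Inducing-point fit: minimise the empirical cost over
    ``phi(x) = sum_k a_k K(x, z_k)`` with penalty
    ``(lambda/N) ||phi||_RKHS^2 + (eps/N) ||a||^2``.

    Stationarity gives the M x M normal system
    ``(Kxz^T Kxz + lambda Kzz + eps I) a = -(Kxz^T r_a + Gxz^T 1)``.
    """
    if eps <= 0:
        raise ValueError("sparse fit requires jitter eps > 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    r_fn = r if r is not None else _zero_reference
    r_a = np.atleast_2d(r_fn(X))[:, alpha]
    Kxz = rbf_matrix(X, Z, spec.length_scale)
    Gxz = rbf_grad(X, Z, spec.length_scale, alpha, K=Kxz)
    Kzz = rbf_matrix(Z, Z, spec.length_scale)
    A = Kxz.T @ Kxz + lam * Kzz + eps * np.eye(Z.shape[0])
    rhs = Kxz.T @ r_a + Gxz.sum(axis=0)
    return -_solve_spd(A, rhs, eps)


# ---------------------------------------------------------------------------
# fitted model container
# ---------------------------------------------------------------------------


@dataclass
class ScoreModel:
    """A fitted per-component score estimator.

    ``coeffs[j]`` holds the coefficient vector for state component
    ``alphas[j]``; evaluation at ``x`` returns
    ``r_a(x) + sum_k coeffs[j][k] * feature_k(x)`` per component.
    """

    klass: str  # "linear" | "kernel" | "sparse"
    dimension: int
    alphas: tuple[int, ...]
    coeffs: Array  # (len(alphas), n_features)
    support: object  # basis list (linear) or support-point array (kernel/sparse)
    spec: Optional[KernelSpec] = None
    reference: Optional[Callable[[Array], Array]] = None
    lam: float = 0.0
    eps: float = 0.0
    cost_minima: Optional[Array] = None  # attained empirical cost per component
    train_score: Optional[Array] = None  # fitted score at the training particles

    def _features(self, Q: Array) -> Array:
        if self.klass == "linear":
            return np.column_stack([b.value(Q) for b in self.support])
        return rbf_matrix(Q, self.support, self.spec.length_scale)

    def _feature_grads(self, Q: Array, alpha: int, F: Optional[Array] = None) -> Array:
        if self.klass == "linear":
            return np.column_stack([b.grad(Q)[:, alpha] for b in self.support])
        return rbf_grad(Q, self.support, self.spec.length_scale, alpha, K=F)

    def phi(self, Q: Array) -> Array:
        """Trial-function part, ``(n, len(alphas))`` — no reference offset."""
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        return self._features(Q) @ self.coeffs.T

    def phi_partial(self, Q: Array) -> Array:
        """Own-component partials ``d_alpha phi^(alpha)(Q)``, ``(n, len(alphas))``."""
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        F = self._features(Q) if self.klass != "linear" else None
        cols = [
            self._feature_grads(Q, a, F) @ self.coeffs[j]
            for j, a in enumerate(self.alphas)
        ]
        return np.column_stack(cols)

    def __call__(self, Q: Array) -> Array:
        return estimate_score(self, Q)


def estimate_score(sm: ScoreModel, Q: Array) -> Array:
    """Evaluate the fitted score at query points: ``r_a(Q_i) + phi_a(Q_i)``.

    Returns an ``(n, len(sm.alphas))`` array (the full ``(n, d)`` score when
    every component was fitted).
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if Q.shape[1] != sm.dimension:
        raise ValueError(
            f"query dimension {Q.shape[1]} does not match model dimension "
            f"{sm.dimension}"
        )
    out = sm.phi(Q)
    if sm.reference is not None:
        out = out + np.atleast_2d(sm.reference(Q))[:, list(sm.alphas)]
    return out


def adaptive_length_scale(X: Array) -> float:
    """Ensemble-adapted RBF length scale: twice the standard deviation of
    the state vector (isotropic convention: the mean of the per-dimension
    sample standard deviations)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least two particles")
    l = 2.0 * float(np.mean(np.std(X, axis=0, ddof=1)))
    return l if l > MIN_LENGTH_SCALE else MIN_LENGTH_SCALE


def _grid_counts(M: int, d: int) -> list[int]:
    # per-dimension counts as equal as possible with product <= M
    counts = [1] * d
    while True:
        i = int(np.argmin(counts))
        trial = counts.copy()
        trial[i] += 1
        if int(np.prod(trial)) > M:
            break
        counts = trial
    return counts


def select_inducing(X: Array, M: int, strategy: str = "uniform_box",
                    rng_seed: int | np.random.Generator | None = 0) -> Array:
    """Place ``M`` inducing points in the axis-aligned bounding box of ``X``.

    ``uniform_box`` draws them i.i.d. uniformly (seeded); ``grid`` lays a
    regular lattice with per-dimension counts as equal as possible.  When
    ``M`` is not a lattice size the nearest feasible size below is used.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if M < 1:
        raise ValueError("M must be >= 1")
    if X.shape[0] < 2:
        raise ValueError("need at least two particles")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    d = X.shape[1]
    if strategy == "uniform_box":
        rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
               else np.random.default_rng(rng_seed))
        return rng.uniform(lo, hi, size=(M, d))
    if strategy == "grid":
        counts = _grid_counts(M, d)
        if int(np.prod(counts)) != M:
            logger.info(
                "grid inducing points: M=%d not a lattice size, using %s (%d points)",
                M, counts, int(np.prod(counts)),
            )
        axes = [
            np.linspace(lo[k], hi[k], counts[k]) if counts[k] > 1
            else np.array([(lo[k] + hi[k]) / 2.0])
            for k in range(d)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([m.ravel() for m in mesh])
    raise ValueError(f"unknown inducing-point strategy {strategy!r}")


# ---------------------------------------------------------------------------
# one-call fitting used by the particle solvers
# ---------------------------------------------------------------------------


def fit_score_model(
    X: Array,
    klass: str = "sparse",
    spec: Optional[KernelSpec] = None,
    lam: float = 1e-3,
    eps: float = 1e-6,
    ridge: float = 0.0,
    basis: Optional[Sequence[BasisFunction]] = None,
    Z: Optional[Array] = None,
    reference: Optional[Callable[[Array], Array]] = None,
    alphas: Optional[Sequence[int]] = None,
    compute_cost: bool = False,
) -> ScoreModel:
    """Fit all requested score components on one ensemble.

    The components share a single factorisation of the relevant Gram
    system.  ``compute_cost=True`` also records the attained empirical cost
    minimum per component (used by the entropy-rate estimator, which
    requires a zero reference function).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    alphas = tuple(range(d)) if alphas is None else tuple(alphas)
    r_fn = reference if reference is not None else None
    r_all = np.atleast_2d((r_fn or _zero_reference)(X))

    # one feature matrix F (n x m) and one own-component gradient matrix per
    # alpha are assembled once, shared by the solve, the cached training-point
    # score and the cost bookkeeping
    if klass == "linear":
        if basis is None:
            basis = affine_basis(d)
        F = np.column_stack([b.value(X) for b in basis])
        m = len(basis)
        if ridge == 0.0 and n < m + 1:
            raise ValueError(f"need N >= m+1 samples ({n} < {m + 1}) without ridge")
        grads = [np.column_stack([b.grad(X)[:, a] for b in basis]) for a in alphas]
        A = F.T @ F + ridge * np.eye(m)
        jitter = 0.0 if ridge else 1e-12
        sm = ScoreModel("linear", d, alphas, np.empty(0), list(basis),
                        reference=r_fn, lam=ridge)
    elif klass in ("kernel", "sparse"):
        if spec is None:
            spec = KernelSpec(length_scale=adaptive_length_scale(X),
                              length_scale_mode="adaptive")
        if klass == "kernel":
            support = X
            F = rbf_matrix(X, X, spec.length_scale)
            A = None  # solved through the eigendecomposition of F below
        else:
            if Z is None:
                raise ValueError("sparse fit requires inducing points Z")
            support = np.atleast_2d(np.asarray(Z, dtype=float))
            F = rbf_matrix(X, support, spec.length_scale)
            Kzz = rbf_matrix(support, support, spec.length_scale)
            A = F.T @ F + lam * Kzz + eps * np.eye(support.shape[0])
        grads = [rbf_grad(X, support, spec.length_scale, a, K=F) for a in alphas]
        jitter = eps
        sm = ScoreModel(klass, d, alphas, np.empty(0), support, spec=spec,
                        reference=r_fn, lam=lam, eps=eps)
    else:
        raise ValueError(f"unknown score class {klass!r}")

    rhs = np.column_stack([
        F.T @ r_all[:, a] + grads[j].sum(axis=0)
        for j, a in enumerate(alphas)
    ])
    if klass == "kernel":
        sm.coeffs = (-_solve_kernel_system(F, lam, rhs)).T
    else:
        sm.coeffs = (-_solve_spd(A, rhs, jitter)).T

    phi_vals = F @ sm.coeffs.T
    sm.train_score = phi_vals + r_all[:, list(alphas)]
    if compute_cost:
        sm.cost_minima = np.array([
            empirical_cost(phi_vals[:, j], grads[j] @ sm.coeffs[j], r_all[:, a])
            for j, a in enumerate(alphas)
        ])
    return sm
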