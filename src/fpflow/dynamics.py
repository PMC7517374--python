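"""Deterministic interacting-particle propagation of Fokker-Planck solutions.

The Fokker-Planck equation is rewritten as a Liouville (continuity)
equation for the deterministic flow ``dX/dt = g(X, t)`` with effective
velocity

    g(x, t) = f(x) - (sigma^2 / 2) grad ln p_t(x)           (additive noise)
    g(x, t) = f(x) - (1/2) div D(x) - (1/2) D(x) grad ln p_t(x)   (general)

so an ensemble of N particles transported by ``g`` carries the density.
The unknown score ``grad ln p_t`` is re-estimated from the ensemble itself
at every time step (module :mod:`fpflow.score`); forward Euler advances
the positions.  Underdamped (Kramers) dynamics are propagated in
position-velocity space with a Verlet-type splitting, the score being
needed only in the velocity block.

Diagnostics recorded along the way: per-dimension cumulants, the mean
squared particle velocity <|g|^2> (which integrates to the relative
entropy decay for equilibrium systems), the entropy-rate estimator built
from the attained score-matching cost minima, and for Langevin runs the
mean kinetic energy and the mean residual |gamma v + (sigma^2/2) s_v|.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .models import LangevinModel, SDEModel
from .score import (
    KernelSpec,
    BasisFunction,
    ScoreModel,
    adaptive_length_scale,
    estimate_score,
    fit_score_model,
    select_inducing,
)

__all__ = [
    "ScoreConfig",
    "SimulationConfig",
    "ParticleEnsemble",
    "LangevinEnsemble",
    "TrajectoryRecord",
    "effective_velocity",
    "simulate_fpe",
    "simulate_langevin",
    "entropy_rate",
    "relative_entropy_trajectory",
]

logger = logging.getLogger(__name__)

Array = np.ndarray


@dataclass
class ScoreConfig:
    """How the score is estimated inside the particle loop.

    ``length_scale`` may be a number or ``"adaptive"`` (twice the ensemble
    standard deviation, recomputed at every refresh).  ``reference`` is
    ``"zero"`` or ``"equilibrium"`` (the Gibbs score, available only for
    equilibrium models).  ``refresh_every`` controls how often the kernel
    hyperparameters (length scale, inducing points) are refreshed; the
    coefficients themselves are refitted at every step regardless.
    """

    klass: str = "sparse"  # "linear" | "kernel" | "sparse"
    lam: float = 1e-3
    jitter: float = 1e-6
    length_scale: Union[float, str] = "adaptive"
    M: int = 100
    inducing_strategy: str = "uniform_box"
    reference: str = "zero"
    basis: Optional[Sequence[BasisFunction]] = None
    ridge: float = 0.0
    refresh_every: int = 1


@dataclass
class SimulationConfig:
    """Particle count, time grid, initial Gaussian, and score settings."""

    N: int = 1000
    dt: float = 1e-3
    T: float = 1.0
    score: ScoreConfig = field(default_factory=ScoreConfig)
    record_every: int = 10
    rng_seed: int = 0
    init_mean: Union[float, Sequence[float]] = 0.0
    init_cov: Union[float, Sequence[Sequence[float]]] = 0.05**2
    # Langevin-only: initial Gaussian for velocities
    init_vel_mean: Union[float, Sequence[float]] = 0.0
    init_vel_cov: Union[float, Sequence[Sequence[float]]] = 0.05**2

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.T < self.dt:
            raise ValueError("T must be at least dt")
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")

    def n_steps(self) -> int:
        return int(np.ceil(self.T / self.dt - 1e-12))


@dataclass
class ParticleEnsemble:
    X: Array
    time: float = 0.0

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if not np.all(np.isfinite(self.X)):
            raise FloatingPointError("non-finite particle positions")


@dataclass
class LangevinEnsemble:
    X: Array
    V: Array
    time: float = 0.0

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        if self.X.shape != self.V.shape:
            raise ValueError("position and velocity arrays must match in shape")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.V))):
            raise FloatingPointError("non-finite ensemble state")

    @property
    def joint(self) -> Array:
        return np.hstack([self.X, self.V])


@dataclass
class TrajectoryRecord:
    """Time-indexed snapshots and diagnostics of one simulation."""

    times: Array
    snapshots: list
    cumulants: pd.DataFrame
    diagnostics: pd.DataFrame
    noise_amplitude: float
    is_equilibrium: bool
    model_name: str = ""
    kind: str = "deterministic"  # "deterministic" | "stochastic"
    seed: int = 0
    config: Optional[dict] = None
    velocity_snapshots: Optional[list] = None

    @property
    def final_ensemble(self) -> Array:
        return self.snapshots[-1]

    def to_csv(self, outdir: Union[str, Path]) -> None:
        """Write snapshot, cumulant, diagnostics tables and a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "model": self.model_name,
            "kind": self.kind,
            "seed": int(self.seed),
            "noise_amplitude": float(self.noise_amplitude),
            "is_equilibrium": bool(self.is_equilibrium),
            "config": self.config,
            "times": [float(t) for t in self.times],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        rows = []
        for t, snap in zip(self.times, self.snapshots):
            for i, x in enumerate(snap):
                rows.append([float(t), i, *map(float, np.atleast_1d(x))])
        d = self.snapshots[0].shape[1]
        pd.DataFrame(
            rows, columns=["time", "particle", *[f"x{k}" for k in range(d)]]
        ).to_csv(outdir / "snapshots.csv", index=False)
        self.cumulants.to_csv(outdir / "cumulants.csv", index=False)
        self.diagnostics.to_csv(outdir / "diagnostics.csv", index=False)


def _sample_gaussian(rng: np.random.Generator, n: int, d: int,
                     mean, cov) -> Array:
    mean = np.broadcast_to(np.atleast_1d(np.asarray(mean, dtype=float)), (d,))
    cov = np.asarray(cov, dtype=float)
    if cov.ndim == 0:
        cov = cov * np.eye(d)
    elif cov.ndim == 1:
        cov = np.diag(cov)
    L = np.linalg.cholesky(cov + 1e-15 * np.eye(d))
    return mean + rng.standard_normal((n, d)) @ L.T


def _cumulant_rows(t: float, X: Array) -> list:
    from .analytics import cumulants as _cum

    table = _cum(X)
    return [
        [t, k, *row] for k, row in enumerate(table)
    ]


def _check_finite(X: Array, step: int, cfg: SimulationConfig) -> None:
    if not np.all(np.isfinite(X)):
        raise FloatingPointError(
            f"non-finite particle state at step {step}; config: N={cfg.N}, "
            f"dt={cfg.dt}, score={cfg.score}"
        )


def effective_velocity(model: SDEModel, X: Array, S: Array) -> Array:
    """Liouville velocity ``g`` on the ensemble given score estimates ``S``.

    Constant isotropic diffusion: ``g = f - (sigma^2/2) S``.  General
    diffusion: ``g = f - (1/2) div D - (1/2) D S`` (the former is the
    exact specialisation at ``D = sigma^2 I``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    F = model.drift_at(X)
    if model.is_constant_isotropic:
        return F - 0.5 * model.noise_amplitude**2 * S
    return (
        F
        - 0.5 * model.diffusion_divergence_ensemble(X)
        - 0.5 * model.diffusion_apply_ensemble(X, S)
    )


def _resolve_reference(model, cfg: ScoreConfig, langevin: bool = False):
    if cfg.reference == "zero":
        return None
    if cfg.reference != "equilibrium":
        raise ValueError(f"unknown reference {cfg.reference!r}")
    if langevin:
        beta = model.inverse_temperature
        d = model.dimension

        def r(Q: Array, beta=beta, d=d) -> Array:
            # joint state (x, v): velocity-block Gibbs score -beta v
            out = np.zeros_like(np.atleast_2d(Q))
            out[:, d:] = -beta * np.atleast_2d(Q)[:, d:]
            return out

        return r
    if model.equilibrium_score is None:
        raise ValueError("equilibrium reference requires an equilibrium model")
    es = model.equilibrium_score
    return lambda Q: np.array([np.asarray(es(q), dtype=float)
                               for q in np.atleast_2d(Q)])


class _ScoreFitter:
    """Refits the score each step, refreshing hyperparameters periodically."""

    def __init__(self, cfg: ScoreConfig, rng: np.random.Generator,
                 reference=None, alphas=None):
        self.cfg = cfg
        self.rng = rng
        self.reference = reference
        self.alphas = alphas
        self._spec: Optional[KernelSpec] = None
        self._Z: Optional[Array] = None
        self._step = 0

    def fit(self, X: Array, compute_cost: bool = False) -> ScoreModel:
        cfg = self.cfg
        refresh = self._step % cfg.refresh_every == 0 or self._spec is None
        if cfg.klass in ("kernel", "sparse") and refresh:
            if cfg.length_scale == "adaptive":
                l = adaptive_length_scale(X)
                self._spec = KernelSpec(length_scale=l, length_scale_mode="adaptive")
            else:
                self._spec = KernelSpec(length_scale=float(cfg.length_scale))
        if cfg.klass == "sparse" and (refresh or self._Z is None):
            self._Z = select_inducing(X, cfg.M, cfg.inducing_strategy, self.rng)
        self._step += 1
        return fit_score_model(
            X,
            klass=cfg.klass,
            spec=self._spec,
            lam=cfg.lam,
            eps=cfg.jitter,
            ridge=cfg.ridge,
            basis=cfg.basis,
            Z=self._Z,
            reference=self.reference,
            alphas=self.alphas,
            compute_cost=compute_cost,
        )


def simulate_fpe(model: SDEModel, cfg: SimulationConfig) -> TrajectoryRecord:
    """Propagate the deterministic particle system for ``ceil(T/dt)`` steps.

    At every step the score is refitted on the current ensemble, the
    effective velocity computed and the positions advanced by forward
    Euler.  Snapshots, cumulants and diagnostics are recorded every
    ``cfg.record_every`` steps (and at the final state).  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    d = model.dimension
    X = _sample_gaussian(rng, cfg.N, d, cfg.init_mean, cfg.init_cov)
    reference = _resolve_reference(model, cfg.score)
    fitter = _ScoreFitter(cfg.score, rng, reference=reference)
    want_entropy = reference is None and model.is_constant_isotropic

    times, snaps, cum_rows, diag_rows = [], [], [], []

    def record(step: int, t: float, X: Array, g: Array,
               sm: Optional[ScoreModel]) -> None:
        times.append(t)
        snaps.append(X.copy())
        cum_rows.extend(_cumulant_rows(t, X))
        speeds = np.linalg.norm(g, axis=1)
        msv = float(np.mean(speeds**2))
        srate = np.nan
        if want_entropy and sm is not None and sm.cost_minima is not None:
            srate = entropy_rate(model, X, sm)
        diag_rows.append([t, msv, float(speeds.max()), srate])

    n_steps = cfg.n_steps()
    t = 0.0
    for step in range(n_steps):
        recording = step % cfg.record_every == 0
        sm = fitter.fit(X, compute_cost=want_entropy and recording)
        g = effective_velocity(model, X, sm.train_score)
        if recording:
            record(step, t, X, g, sm)
        X = X + cfg.dt * g
        t = (step + 1) * cfg.dt
        _check_finite(X, step + 1, cfg)
    # final state: fit once more for its diagnostics
    sm = fitter.fit(X, compute_cost=want_entropy)
    g = effective_velocity(model, X, sm.train_score)
    record(n_steps, t, X, g, sm)

    cum = pd.DataFrame(
        cum_rows, columns=["time", "dim", "mean", "std", "skewness", "kurtosis"]
    )
    diag = pd.DataFrame(
        diag_rows, columns=["time", "mean_sq_velocity", "max_speed", "entropy_rate"]
    )
    return TrajectoryRecord(
        times=np.asarray(times),
        snapshots=snaps,
        cumulants=cum,
        diagnostics=diag,
        noise_amplitude=model.noise_amplitude,
        is_equilibrium=model.is_equilibrium,
        model_name=model.name,
        kind="deterministic",
        seed=cfg.rng_seed,
    )


def simulate_langevin(model: LangevinModel, cfg: SimulationConfig) -> TrajectoryRecord:
    """Propagate underdamped Langevin particles with a Verlet-type scheme.

    The score is fitted on the joint (position, velocity) ensemble in 2d
    dimensions, but only the d velocity components are estimated.  One
    step (score refit once per step, after the position update):

        v_half = v + (dt/2) F(x, v)      with F = -gamma v + f(x) - (sigma^2/2) s_v
        x'     = x + dt v_half
        refit score on (x', v_half)
        v'     = v_half + (dt/2) F(x', v_half)

    In the Hamiltonian limit (s_v = -beta v exactly) this reduces to
    standard velocity Verlet.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    d = model.dimension
    X = _sample_gaussian(rng, cfg.N, d, cfg.init_mean, cfg.init_cov)
    V = _sample_gaussian(rng, cfg.N, d, cfg.init_vel_mean, cfg.init_vel_cov)
    reference = _resolve_reference(model, cfg.score, langevin=True)
    alphas = tuple(range(d, 2 * d))  # velocity block of the joint state
    fitter = _ScoreFitter(cfg.score, rng, reference=reference, alphas=alphas)
    gamma, s2 = model.dissipation, model.noise_amplitude**2

    def vel_force(X: Array, V: Array, sm: ScoreModel,
                  at_train: bool = False) -> tuple[Array, Array]:
        # at_train: the model was fitted on exactly this state, so the
        # cached training-point score applies
        Sv = sm.train_score if at_train else estimate_score(sm, np.hstack([X, V]))
        return -gamma * V + model.force_at(X) - 0.5 * s2 * Sv, Sv

    times, snaps, vsnaps, cum_rows, diag_rows = [], [], [], [], []

    def record(t: float, X: Array, V: Array, Sv: Array) -> None:
        times.append(t)
        snaps.append(X.copy())
        vsnaps.append(V.copy())
        joint = np.hstack([X, V])
        cum_rows.extend(_cumulant_rows(t, joint))
        ke = float(np.mean(0.5 * np.sum(V**2, axis=1)))
        resid = float(np.mean(np.linalg.norm(gamma * V + 0.5 * s2 * Sv, axis=1)))
        diag_rows.append([t, ke, resid])

    n_steps = cfg.n_steps()
    sm = fitter.fit(np.hstack([X, V]))
    t = 0.0
    for step in range(n_steps):
        F, Sv = vel_force(X, V, sm)
        if step % cfg.record_every == 0:
            record(t, X, V, Sv)
        V_half = V + 0.5 * cfg.dt * F
        X = X + cfg.dt * V_half
        sm = fitter.fit(np.hstack([X, V_half]))
        F2, _ = vel_force(X, V_half, sm, at_train=True)
        V = V_half + 0.5 * cfg.dt * F2
        t = (step + 1) * cfg.dt
        _check_finite(np.hstack([X, V]), step + 1, cfg)
    _, Sv = vel_force(X, V, sm)
    record(t, X, V, Sv)

    cum = pd.DataFrame(
        cum_rows, columns=["time", "dim", "mean", "std", "skewness", "kurtosis"]
    )
    diag = pd.DataFrame(
        diag_rows, columns=["time", "mean_kinetic_energy", "mean_score_residual"]
    )
    return TrajectoryRecord(
        times=np.asarray(times),
        snapshots=snaps,
        cumulants=cum,
        diagnostics=diag,
        noise_amplitude=model.noise_amplitude,
        is_equilibrium=True,
        model_name=model.name,
        kind="deterministic",
        seed=cfg.rng_seed,
        velocity_snapshots=vsnaps,
    )


def entropy_rate(model: SDEModel, X: Array, sm: ScoreModel) -> float:
    """Entropy-rate estimator from the attained score-matching minima.

    ``dS/dt ~ -(sigma^2/2) sum_a min L_a + (1/N) sum_i div f(X_i)``.
    The identity linking the cost minimum to the entropy production term
    holds only for a zero reference function.
    """
    if sm.reference is not None:
        raise ValueError("entropy-rate estimator requires a zero reference function")
    if sm.cost_minima is None:
        raise ValueError("score model was fitted without cost bookkeeping")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    prod = -0.5 * model.noise_amplitude**2 * float(np.sum(sm.cost_minima))
    flux = float(np.mean(model.drift_divergence_ensemble(X)))
    return prod + flux


def relative_entropy_trajectory(record: TrajectoryRecord, D0: float) -> pd.Series:
    """Relative entropy to equilibrium along a run:
    ``D(t) = D0 - (2/sigma^2) int_0^t <|g|^2> ds`` (trapezoidal rule).

    Valid only for equilibrium models; non-increasing by construction
    since the integrand is non-negative.
    """
    if not record.is_equilibrium:
        raise ValueError("relative entropy requires an equilibrium model")
    msv = record.diagnostics["mean_sq_velocity"].to_numpy()
    t = record.times
    integral = cumulative_trapezoid(msv, t, initial=0.0)
    D = D0 - 2.0 / record.noise_amplitude**2 * integral
    return pd.Series(D, index=t, name="relative_entropy")
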