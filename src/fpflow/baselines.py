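"""Stochastic Monte-Carlo baselines.

Direct simulation of the underlying SDEs: Euler-Maruyama for first-order
systems (Ito convention, ``X <- X + dt f(X) + sqrt(dt) S(X) xi`` with
``S S^T = D``) and a BAOAB splitting for underdamped Langevin dynamics
(exact Ornstein-Uhlenbeck velocity refresh between Verlet half-kicks).
Both record the same snapshot/cumulant schedule as the deterministic
solver so runs can be compared table-for-table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import (
    SimulationConfig,
    TrajectoryRecord,
    _check_finite,
    _cumulant_rows,
    _sample_gaussian,
)
from .models import LangevinModel, SDEModel

__all__ = ["euler_maruyama", "stochastic_langevin"]

Array = np.ndarray


def euler_maruyama(model: SDEModel, cfg: SimulationConfig) -> TrajectoryRecord:
    """Euler-Maruyama integration of ``dX = f dt + S(X) dB`` (seeded)."""
    rng = np.random.default_rng(cfg.rng_seed)
    d = model.dimension
    X = _sample_gaussian(rng, cfg.N, d, cfg.init_mean, cfg.init_cov)
    times, snaps, cum_rows = [], [], []

    def record(t: float, X: Array) -> None:
        times.append(t)
        snaps.append(X.copy())
        cum_rows.extend(_cumulant_rows(t, X))

    n_steps = cfg.n_steps()
    sqdt = np.sqrt(cfg.dt)
    t = 0.0
    for step in range(n_steps):
        if step % cfg.record_every == 0:
            record(t, X)
        drift = model.drift_at(X)
        if model.noise_amplitude == 0.0 and model.diffusion is None:
            X = X + cfg.dt * drift
        else:
            xi = rng.standard_normal((cfg.N, d))
            X = X + cfg.dt * drift + sqdt * model.diffusion_sqrt_apply_ensemble(X, xi)
        t = (step + 1) * cfg.dt
        _check_finite(X, step + 1, cfg)
    record(t, X)

    cum = pd.DataFrame(
        cum_rows, columns=["time", "dim", "mean", "std", "skewness", "kurtosis"]
    )
    diag = pd.DataFrame({"time": times})
    return TrajectoryRecord(
        times=np.asarray(times),
        snapshots=snaps,
        cumulants=cum,
        diagnostics=diag,
        noise_amplitude=model.noise_amplitude,
        is_equilibrium=model.is_equilibrium,
        model_name=model.name,
        kind="stochastic",
        seed=cfg.rng_seed,
    )


def stochastic_langevin(model: LangevinModel, cfg: SimulationConfig) -> TrajectoryRecord:
    """BAOAB integration of the underdamped Langevin SDE.

    B: half velocity kick with the force; A: half position drift;
    O: exact Ornstein-Uhlenbeck velocity update with decay ``exp(-gamma dt)``
    and stationary variance ``sigma^2 / (2 gamma)``; then A and B again.
    In the limit ``gamma -> 0``, ``sigma -> 0`` the O step is the identity
    and the scheme reduces to velocity Verlet.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    d = model.dimension
    gamma, sigma = model.dissipation, model.noise_amplitude
    X = _sample_gaussian(rng, cfg.N, d, cfg.init_mean, cfg.init_cov)
    V = _sample_gaussian(rng, cfg.N, d, cfg.init_vel_mean, cfg.init_vel_cov)
    times, snaps, vsnaps, cum_rows, diag_rows = [], [], [], [], []

    def record(t: float, X: Array, V: Array) -> None:
        times.append(t)
        snaps.append(X.copy())
        vsnaps.append(V.copy())
        cum_rows.extend(_cumulant_rows(t, np.hstack([X, V])))
        diag_rows.append([t, float(np.mean(0.5 * np.sum(V**2, axis=1)))])

    c1 = np.exp(-gamma * cfg.dt)
    c2 = sigma * np.sqrt((1.0 - c1**2) / (2.0 * gamma)) if gamma > 0 else 0.0
    n_steps = cfg.n_steps()
    t = 0.0
    for step in range(n_steps):
        if step % cfg.record_every == 0:
            record(t, X, V)
        V = V + 0.5 * cfg.dt * model.force_at(X)          # B
        X = X + 0.5 * cfg.dt * V                           # A
        V = c1 * V + c2 * rng.standard_normal((cfg.N, d))  # O
        X = X + 0.5 * cfg.dt * V                           # A
        V = V + 0.5 * cfg.dt * model.force_at(X)           # B
        t = (step + 1) * cfg.dt
        _check_finite(np.hstack([X, V]), step + 1, cfg)
    record(t, X, V)

    cum = pd.DataFrame(
        cum_rows, columns=["time", "dim", "mean", "std", "skewness", "kurtosis"]
    )
    diag = pd.DataFrame(diag_rows, columns=["time", "mean_kinetic_energy"])
    return TrajectoryRecord(
        times=np.asarray(times),
        snapshots=snaps,
        cumulants=cum,
        diagnostics=diag,
        noise_amplitude=sigma,
        is_equilibrium=True,
        model_name=model.name,
        kind="stochastic",
        seed=cfg.rng_seed,
        velocity_snapshots=vsnaps,
    )
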