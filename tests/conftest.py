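"""Shared fixtures and the brute-force quadratic oracle for score fits."""

from __future__ import annotations

import numpy as np
import pytest

from fpflow.score import rbf_eval, KernelSpec


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def naive_features(X: np.ndarray, centers: np.ndarray, spec: KernelSpec,
                   alpha: int) -> tuple[np.ndarray, np.ndarray]:
    """Kernel feature values and own-component partials via scalar ``rbf_eval``
    calls — a deliberately independent code path from the vectorised Gram
    routines used by the fitters."""
    n, m = X.shape[0], centers.shape[0]
    Phi = np.empty((n, m))
    dPhi = np.empty((n, m))
    for i in range(n):
        for k in range(m):
            val, grad = rbf_eval(X[i], centers[k], spec)
            Phi[i, k] = val
            dPhi[i, k] = grad[alpha]
    return Phi, dPhi


def quadratic_oracle_minimum(J, m: int) -> tuple[np.ndarray, float]:
    """Dense minimiser of an exactly-quadratic objective ``J: R^m -> R``.

    Extracts the Hessian and gradient by evaluating ``J`` at coordinate
    vectors (exact for quadratics — no finite-difference error) and solves
    the resulting linear system directly.
    """
    c = J(np.zeros(m))
    e = np.eye(m)
    Jp = np.array([J(e[i]) for i in range(m)])
    Jm = np.array([J(-e[i]) for i in range(m)])
    g = 0.5 * (Jp - Jm)
    H = np.empty((m, m))
    for i in range(m):
        H[i, i] = Jp[i] + Jm[i] - 2.0 * c
        for j in range(i):
            H[i, j] = H[j, i] = J(e[i] + e[j]) - Jp[i] - Jp[j] + c
    # minimum-norm solve: kernel Gram null spaces leave the objective exactly
    # flat, so the stationary system may be (numerically) singular
    a_star = np.linalg.lstsq(H, -g, rcond=1e-14)[0]
    return a_star, float(J(a_star))
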