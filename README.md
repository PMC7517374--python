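# fpflow

Deterministic interacting-particle solutions of Fokker–Planck equations
through gradient–log–density (score) estimation.

## The problem

The Fokker–Planck equation (FPE)

```
∂p_t/∂t = −∇·[f(x) p_t(x)] + (σ²/2) ∇²p_t(x)
```

describes how the probability density of an SDE state
`dX = f(X) dt + σ dB` evolves. Closed-form solutions exist only for
linear drifts; direct Monte-Carlo simulation of the SDE is unbiased but
its cumulant trajectories fluctuate strongly unless the number of
trajectories is large. `fpflow` implements the alternative: the FPE is
rewritten as a Liouville (continuity) equation for the *deterministic*
flow

```
dX/dt = g(X, t),    g(x, t) = f(x) − (σ²/2) ∇ln p_t(x),
```

so an ensemble of N particles transported by `g` carries the density with
the only randomness coming from the initial draw. The unknown score
`∇ln p_t` is re-estimated from the ensemble at every time step by
score matching: each component `∂_α ln p` is the minimiser of

```
L_α[φ] = E_p[ φ² + 2 r_α φ + 2 ∂_α φ ],
```

an expectation that involves no normalising constant (`r` is an optional
reference function, zero by default). Over any linearly-parametrised
trial family the empirical cost is quadratic, so the fit is one symmetric
linear solve. Three families are provided: a fixed **linear** basis
(exact for Gaussian densities), the full **kernel** (RKHS) family with an
RBF kernel and penalty `(λ/N)‖φ‖²`, and a **sparse** inducing-point
family `φ(x) = Σ_k a_k K(x, z_k)` that reduces the per-step solve from
N×N to M×M. State-dependent diffusion `D(x)` (an extra `−½∇·D − ½D∇ln p`
drift) and second-order (Kramers/underdamped Langevin) dynamics, where
the score is needed only in the velocity block, are supported, along with
Euler–Maruyama and BAOAB stochastic baselines, analytic Gaussian
propagation for linear SDEs, Gaussian KL, empirical 1-Wasserstein
distance, cumulant tables, and entropy-rate / relative-entropy
diagnostics.

Intended users: anyone simulating low- to moderate-dimensional stochastic
dynamics — chemical-network, neural or climate models — who wants smooth,
low-variance density trajectories from modest particle numbers.

## Worked example

Two-dimensional linear process `f(x) = −x`, σ = 1, 1000 particles,
sparse score with M = 200 inducing points, compared with the analytic
Gaussian solution:

```python
import numpy as np
from fpflow import (SimulationConfig, ScoreConfig, simulate_fpe,
                    benchmark_model, propagate_linear_gaussian,
                    GaussianState, gaussian_kl)

model = benchmark_model("ou", dimension=2)            # dX = -X dt + dB
cfg = SimulationConfig(N=1000, dt=1e-3, T=3.0, rng_seed=1,
                       init_mean=[0.5, 0.5], init_cov=0.05**2,
                       score=ScoreConfig(klass="sparse", M=200))
rec = simulate_fpe(model, cfg)

analytic = propagate_linear_gaussian(
    -np.eye(2), 1.0, GaussianState([0.5, 0.5], 0.05**2 * np.eye(2)),
    0.01, 3.0)
by_t = {round(g.time, 6): g for g in analytic}
kls = [gaussian_kl(GaussianState(X.mean(axis=0), np.cov(X.T)), by_t[round(t, 6)])
       for t, X in zip(rec.times, rec.snapshots)]
print(f"time-averaged KL: {np.mean(kls):.2e}")
print(f"stationary KL:    {kls[-1]:.2e}")
```

Output:

```
time-averaged KL: 1.39e-05
stationary KL:    2.93e-07
```

Both divergences are far below 10⁻², i.e. the 1000-particle deterministic
ensemble tracks the analytic Gaussian essentially exactly; a stochastic
simulation of the same size leaves a sampling error in the stationary
mean roughly two orders of magnitude larger.

A command-line interface drives the same machinery:

```
fpe simulate --model double_well --N 500 --M 150 --T 3 --out run/
fpe baseline --model double_well --N 500 --T 3 --out run_s/
fpe compare  --run-a run/simulate --run-b run_s/baseline --metric w1
fpe suite ou_dims
fpe run --config src/fpflow/presets/ou2d.yaml
```

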