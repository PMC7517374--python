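# Methods

## Model and procedure

`fpflow` simulates the density evolution of Itô diffusions
`dX = f(X) dt + S(X) dB`, `S Sᵀ = D`, by transporting particles with the
deterministic Liouville velocity

* additive isotropic noise: `g(x,t) = f(x) − (σ²/2) ∇ln p_t(x)`,
* general diffusion: `g(x,t) = f(x) − ½∇·D(x) − ½D(x) ∇ln p_t(x)`,

where the score `∇ln p_t` is replaced by a statistical estimate computed
from the ensemble itself at every step. The estimator is variational:
component α of the score equals `r_α + argmin_φ E[φ² + 2 r_α φ + 2 ∂_α φ]`
for any reference function `r` (zero by default; the Gibbs score
`(2/σ²) f` for equilibrium models links the flow to kernel Stein
methods). Expectations are taken under the empirical measure, making the
cost quadratic in the coefficients of a linear trial family. Each of the
d components is fitted independently; the per-component solves share one
matrix factorisation.

Assumptions: Itô convention throughout; `D(x)` symmetric PSD; densities
decay fast enough at infinity for the integration-by-parts identity
behind the cost (true for all bundled benchmarks); the mean-field limit
(exactness as N → ∞) requires a consistent estimator, which in turn
requires the kernel length scale to track the ensemble spread.

## Estimator classes and numerics

* **linear** — fixed basis; normal equations `C a = −b` with
  `C = ΦᵀΦ`. With the affine basis `{1, x_1, …, x_d}` the Gaussian score
  is exactly representable, so linear-SDE problems are solved to
  sampling accuracy. An optional ridge penalty `ρ‖a‖²` lifts the
  `N ≥ m+1` requirement.
* **kernel** — full RKHS family with the RBF kernel
  `K(x,y) = exp(−‖x−y‖²/(2l²))` and penalty `(λ/N)‖φ‖²_RKHS`. The
  stationary system `(K² + λK) a = −(K r_α + Gᵀ1)` is solved through the
  eigendecomposition of `K`, inverting `μ² + λμ` per mode and truncating
  modes below `10⁻¹² μ_max`: forming `K²` explicitly and factorising
  would square the condition number and lose genuine small-eigenvalue
  curvature, while the objective is exactly flat on K's null space so
  truncation is the correct pseudo-inverse behaviour.
* **sparse** — the default inside the particle loop:
  `φ(x) = Σ_{k≤M} a_k K(x, z_k)` with total penalty
  `(λ/N)‖φ‖²_RKHS + (ε/N)‖a‖²`. The typeset formula for this solve in
  the source material is ambiguous, so the estimator is derived directly
  from the variational objective: stationarity gives the M×M system
  `(Kxzᵀ Kxz + λ Kzz + ε I) a = −(Kxzᵀ r_α + Gxzᵀ 1)`, validated in the
  tests against a brute-force dense quadratic minimisation. Symmetric
  systems use Cholesky with escalating jitter (ε, 10ε, 100ε) before
  failing, since Gram matrices degenerate when particles cluster.

Defaults and units (all dimensionless, matching the benchmark
conventions): λ = 10⁻³, jitter ε = 10⁻⁶ (the smallest value that keeps
the benchmark Gram factorisations stable), adaptive length scale
`l = 2 · mean_α std(X^(α))` with floor 10⁻³ (the "twice the standard
deviation of the state vector" rule; the mean-over-dimensions convention
resolves its ambiguity for d > 1 — per-dimension scaling is out of
scope), M = 100–200 inducing points drawn uniformly from the ensemble
bounding box (or on a regular lattice with per-dimension counts as equal
as possible), refreshed together with `l` at every step
(`refresh_every` exposes cheaper refresh schedules but their effect is
uncharacterised).

## Time stepping

Forward Euler with dt = 10⁻³ for first-order dynamics; the score is
refitted once per step. Underdamped (Kramers) dynamics use a
position-Verlet variant: half velocity kick with
`F = −γv + f(x) − (σ²/2) ŝ_v`, full position drift, score refit on the
mid-step state, second half kick. This reduces to standard velocity
Verlet in the Hamiltonian limit (where `ŝ_v → −βv` cancels the
friction), which is where its energy-conservation property matters; the
score is deliberately not refitted at substages (double cost, no
guidance on benefit). The joint (x, v) state is the estimation space but
only the d velocity components are fitted. Any NaN/Inf aborts the run
with the step index and configuration; there is no silent clipping.

Stochastic baselines: Euler–Maruyama with the principal matrix square
root of `D(x)` for the noise, and a BAOAB splitting for underdamped
dynamics (exact Ornstein–Uhlenbeck velocity refresh between Verlet
half-kicks) as a standard quasi-symplectic integrator at the same dt.

## Diagnostics

* Per-dimension cumulants (mean, std, skewness, **excess** kurtosis — a
  normal distribution scores 0; stated because conventions differ).
* Entropy rate: `−(σ²/2) Σ_α min L_α + ⟨∇·f⟩`, valid only for zero
  reference (the identity between the attained cost minimum and the
  entropy production term needs r ≡ 0); enforced with an error.
* Relative entropy to equilibrium:
  `D(t) = D(0) − (2/σ²) ∫₀ᵗ ⟨‖g‖²⟩ ds` (trapezoidal rule over the
  recording grid), non-increasing by construction; `D(0)` is an input
  (closed form for Gaussian initial conditions, quadrature otherwise).
* Generator check: for observables whose gradient lies in the span of
  the linear basis, the empirical `d⟨h⟩/dt` along the flow equals the
  generator expectation `⟨f·∇h + (σ²/2)∇²h⟩` with zero remainder; used
  as a property test of the transport.
* 1-Wasserstein distance: exact sorted-quantile coupling in 1-D; exact
  linear-assignment transport in higher dimension on at most 2000 points
  per side, larger ensembles being subsampled uniformly with a recorded
  seed (deterministic and unbiased conditional on the subsample;
  sliced/entropic approximations were rejected for being either
  stochastic or biased). Repeated evaluations with different seeds give
  the dispersion.
* Gaussian KL in closed form; analytic linear-SDE moments by integrating
  `ṁ = Am`, `Ċ = AC + CAᵀ + σ²I` at tolerance 10⁻¹⁰.

## Benchmarks

`benchmark_model` constructs: a stable linear process (default
`A = −I`, any dimension; symmetric A carries its quadratic potential), a
bistable system `f = −4x³ + 4x` (potential `x⁴ − 2x²`), a bistable
system with multiplicative noise `D(x) = sin²x` and drift `4(x − x³)`,
the Lorenz system at the classic chaotic parameters (10, 28, 8/3) with
additive noise (default amplitude 2 — "moderate" relative to the
attractor scale), and underdamped harmonic (`f = −4x`) and double-well
Langevin systems. Where the exact appendix parameter values of the
original studies are not available, these defaults are configurable
stand-ins. Initial ensembles are seeded Gaussians; the bundled presets
use N(0, 0.05²) and N((0.5, 0.5), 0.05² I).

## What the tests show — and what they do not

The synthetic benchmarks have known drifts, Gaussian initial conditions
and (where used as references) analytic or large-N stochastic solutions.
Passing tests demonstrate: correctness of each estimator against an
independent dense quadratic oracle; exactness of the linear class on
Gaussian problems; Gaussian-KL below 10⁻² against analytic solutions in
dimensions 2–5; a ≥100× stationary-mean accuracy gain over stochastic
simulation of equal size; equal-or-better transport distance at 1/5 the
particle count on the bistable system; equipartition and residual decay
for underdamped dynamics; and the λ → ∞ kernel-Stein limit. They do not
show performance on real data with unknown, rough drifts, in dimensions
beyond 5 (accuracy is known to degrade with dimension), or for densities
with heavy tails where the bounding-box inducing-point rule under-covers.

## Study sizes

Tests and the acceptance script run desk-scale versions of the benchmark
studies: N = 500–2000 particles (reference ensembles 20000), horizons
T = 2–10, and 2–5 seeds per median, rather than the 10⁴–10⁵-particle,
many-repetition originals. The asserted tolerances are unchanged; at
these sizes every headline quantity is orders of magnitude inside its
threshold, so the reduction does not mask marginal behaviour.

## Known limitations

* Accuracy of covariance estimates degrades with dimension; more
  inducing points (M = 200 rather than 100) recover much of it.
* The full-kernel class scales as O(N³) per step and component; it is
  practical only for small ensembles or one-off fits.
* Uniform/grid inducing-point placement wastes points for strongly
  non-uniform densities; clustering-based placement is future work.
* The entropy-rate identity requires r ≡ 0 and constant isotropic noise;
  it is recorded as NaN otherwise.
* No Stratonovich interpretation, jump processes, higher-order or
  adaptive integrators, JKO/implicit Wasserstein stepping, or
  neural-network score models.
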