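# Methods

This note records the models, conventions and numerical choices behind
`hessgas`, and what the synthetic testbed does and does not probe.

## Coordinates and units

Everything is in Hartree atomic units with ħ = 1. Model surfaces are
defined in mass-scaled coordinates (coordinates carry √mass, so the
kinetic energy is ½ p·p and all frequencies are in a.u. of energy);
`PotentialSurface.masses` supports non-unit masses where needed, and the
`morse_1d` examples fold a physical reduced mass into the width
parameter `a → a/√m` instead. Conversion used for spectra:
1 hartree = 219474.63 cm⁻¹; XYZ files store Å with
1 Å = 1/0.529177210903 bohr.

## Model surfaces

- `harmonic_nd(ω)` — separable, constant Hessian `diag(ω²)`; the
  exactness limit every method must reproduce to machine precision.
- `morse_1d(D, a)` — `V = D(1 − e^{−aq})²` with analytic ladder
  `E_n = ω₀(n+½) − (ω₀(n+½))²/(4D)`, `ω₀ = a√(2D/m)`; the anharmonic
  oracle for spectra. The spectroscopy tests use D = 0.176, a = 1.02
  with reduced mass 1744 a.u. (an HF-like stretch, ω₀ ≈ 3180 cm⁻¹).
- `coupled_morse_2d` — two Morse oscillators coupled through
  `λ u₁ u₂`, `u_k = 1 − e^{−a_k q_k}`; its off-diagonal Hessian element
  `λ a₁ a₂ e^{−a₁q₁}e^{−a₂q₂}` is position-dependent and vanishes
  identically at λ = 0 (separability check).
- `quartic_tangle_nd` — `V = Σ_k b_k (q_k² − c²)² + g Σ_{k<l} q_k² q_l²`
  with `b_k = b(1 + 0.1k)`. Defaults (b = 2.2e-9, c = 15, g = 2e-10)
  were chosen once, on physical grounds: well frequencies
  ω_k = √(8 b_k) c ≈ 2e-3 a.u. (molecular low-frequency modes), barrier
  b c⁴ ≈ 1.1e-4 hartree well below the per-mode zero-point energy
  ω/2 ≈ 1e-3 hartree so that zero-point-scale trajectories hop between
  the 2^n wells, and a coupling weak enough (2g·n·c² < 4bc²) not to
  reshape the well structure — a stronger coupling was observed to
  create spurious soft minima and was rejected for that reason, not for
  any effect on method rankings. This is the "tangle": Husimi ensembles
  on it cross and overlap, the regime where landmark clustering should
  beat along-the-path reuse.

## Dynamics

NVE propagation uses the fourth-order Forest–Ruth drift–kick
composition (θ = 1/(2−2^{1/3}); drifts θ/2, (1−θ)/2, (1−θ)/2, θ/2,
kicks θ, 1−2θ, θ, 0). A record with `n_steps` updates stores
`n_steps + 1` states including the initial one; budget arithmetic that
mirrors "150 Hessians out of 3000 time-steps" is exercised on
3000-row slices. Energy conservation on the default molecular-scale
runs (dt = 10 a.u., ω·dt ≈ 0.02) is ~5e-7 relative and halving dt
reduces the error ≈16×, confirming fourth order. Instability (|E|
growth beyond 1e3×) raises an error carrying the step index.

Normal-mode analysis minimizes with BFGS (analytic gradients,
‖∇V‖ < 1e-8), diagonalizes the mass-weighted Hessian, clips
ω² ∈ [−1e-8, 1e-10) to zero (saddle beyond that tolerance is an
error) and excludes near-zero modes (ω² < 1e-10) from the vibrational
count. Initial conditions: position at the minimum, kinetic energy
(n_k+½)ħω_k per mode (one quantum on a target mode on request);
Husimi ensembles draw q and p per mode from independent Gaussians with
variances ħ/(2ω) and ħω/2 from a single seeded generator.

## Neural gas

Training vectors (coordinates, optionally concatenated with gradients)
are min–max scaled per component to [0,1]; degenerate components map to
0.5. Neurons initialize on trajectory points at stride ⌊j·n/m⌋. Each
epoch visits every point once in a seeded random permutation; each
visit updates *all* neurons with weight α(τ)e^{−K_j/λ(τ)}, where K_j
counts strictly closer neurons (ties to the lower index — determinism)
and both α and λ decay geometrically `g(τ) = g₀(g₁/g₀)^{τ/τ_max}`
between the standard endpoints α: 0.3→0.05, λ: 30→0.01. The epoch count
is not part of the standard recipe; the default of 40 was fixed ahead
of the comparisons as sufficient for the schedule to reach its frozen
endpoint (e^{−1/λ_final} ≈ e^{−100}: only the winning neuron still
moves). After training, a single assign-then-move pass places each
neuron at its Voronoi cell's centroid (empty cells are flagged and left
in place; an iterate-to-convergence Lloyd mode exists but is off by
default). The discretized quantization error is the **mean squared**
member-to-neuron distance, for which the centroid is the exact
per-cell minimizer — that choice makes the refinement provably
monotone. One exact Hessian is computed per neuron geometry
(back-transformed through the coordinate block only, in the
gradient-extended space) and every step inherits its neuron's Hessian.

The ranking convention follows the original competitive-learning
formulation — for each sampled data point the *neurons* are ranked by
distance — which is the reading consistent with the update rule's role
for K; the alternative (ranking trajectory points per neuron) would
make the per-visit update ill-defined.

## Database and update comparators

DBH sweeps steps in time order; a hit requires every coordinate
difference strictly below ρ (boundary = miss, for determinism), the
best hit minimizes the max component deviation, and misses append to
the database. Distances are taken in the trajectory's native
coordinates, so ρ is system-dependent; `rho_for_budget` bisects to a
requested budget within ±5 %. A mean-absolute-difference criterion is
also provided and is, provably, never stricter at equal ρ. Lookup is a
vectorized linear scan (equivalent to the mode-after-mode early-exit
scan; spatial indexing is out of scope below ~1e4 steps).

CFD updates chain from the latest state and refresh exactly every
`refresh_every` steps. SR1 and PSB satisfy the secant condition
(H+ΔH)ΔX = ΔG identically; the Bofill weight
λ = 1 − (R·ΔX)²/(‖R‖²‖ΔX‖²) (clipped to [0,1]) moves the mixture onto
the PSB branch exactly when the SR1 denominator R·ΔX degenerates.
Zero-length steps return ΔH = 0 with a warning; every emitted matrix is
symmetrized.

## Error metric and comparison harness

σ_Hess is the mean absolute error per Hessian element per step; the
harness evaluates it in Cartesian coordinates, applying the
mass-weighted back-transform `M^{1/2} L H_nm Lᵀ M^{1/2}` when a
normal-mode basis is supplied (the model surfaces are already
mass-scaled Cartesian, where the transform is the identity). Matched
budgets: NGas gets m neurons, DBH gets ρ bisected to m ± 5 %, CFD
refreshes every ⌈N/m⌉ steps (per ensemble member). Seeds are aggregated
by median — robust to the stochastic training order; DBH and CFD are
deterministic.

## Semiclassical layer

The monodromy matrix is propagated as dM/dt = A(t)M with
A = [[0, −H(t)], [I, 0]] in (δp, δq) block order, using the same
Forest–Ruth composition as the trajectory with H held at its step
value. Every kick and drift is a unit-determinant shear, so
symplecticity is exact by construction and the monitored
|det(MᵀM) − 1| measures only determinant round-off: < 1e-12 on
harmonic runs, and growing like ε‖M‖⁴ (to ~1e-2 over 1e4 a.u.) on the
chaotic quartic tangle where ‖M‖ reaches ~1e4 — reported, not
enforced, and identical in character for exact and approximated
Hessians.

Coherent states use the width matrix γ = diag(ω_k) of harmonic
frequencies: ⟨x|pq⟩ ∝ exp(−(x−q)ᵀγ(x−q)/2 + ipᵀ(x−q)), giving
⟨p₁q₁|p₂q₂⟩ = exp(−¼Δqᵀγ Δq − ¼Δpᵀγ⁻¹Δp + (i/2)(p₁+p₂)·(q₁−q₂)).
The Herman–Kluk prefactor is evaluated as
C_t = √det{½(M_qq + γ⁻¹M_ppγ + iγ⁻¹M_pq − iM_qpγ)} with the phase
φ_t = ½·arg det unwound continuously across steps (caustics — vanishing
modulus — are flagged without breaking the unwinding). This sign
convention is pinned by the harmonic exact limit: a single trajectory
with the reference coherent state at its initial phase-space point must
reproduce the survival amplitude e^{−iωt/2}e^{|α|²(e^{−iωt}−1)}, i.e.
peaks at exactly (n+½)ω, which the test suite asserts to grid
resolution. The classical action is accumulated from the stored
Lagrangian by cumulative Simpson quadrature; the time integral of the
spectrum uses trapezoid weights on the stored grid.

The spectrum is the few-trajectory (multiple-coherent-states) form:
single time integral, modulus squared, no phase-space Monte Carlo. The
reference state defaults to the coherent state at the trajectory's
initial point; ±-momentum sign patterns build mode-filtering
superpositions. Energies are absolute (ZPE visible). Following the
standard practice for level-specific accuracy, each level is best
resolved by a trajectory whose kinetic energy matches that level's
harmonic estimate; the Morse fundamental check therefore uses one
zero-point trajectory for E₀ and a one-quantum trajectory for E₁
(measured error 0.08 %, dominated by the semiclassical approximation
itself, not the grid). The quasi-classical spectrum is the undamped
velocity–velocity power spectrum; no artificial decay filter is
applied, so linewidths are Fourier-limited at 2π/T.

Divide-and-conquer utilities: the projected potential
V(q̃_t, q_t^rest) − V(q̃_eq, q_t^rest) (exact for separable potentials),
and mode-subspace detection by thresholding the time-averaged Hessian
at 8.0e-6 a.u. (default) and taking connected components of the
surviving off-diagonal couplings.

## Problem sizes

Default desk-scale conditions: single trajectories of 3000 steps at
dt = 10 a.u. with 150 neurons (one exact Hessian per 20 steps), and
ensembles of 50 Husimi-sampled trajectories × 200 steps with a budget
of 100 (1 % of steps) — the drastic-budget regime where the methods
separate. Monodromy/spectral checks use 3000-step runs; the monodromy
closed-form check uses dt = 1 so that the composition error
(∝(ωdt)⁴) sits below the 1e-6 comparison threshold at ωt = π/2.

## What the synthetic testbed does not show

- Surfaces are low-dimensional (≤ 12) and analytic; ab initio noise,
  rotational/translational zero modes of real Cartesian geometries, and
  electronic-structure failure modes are not represented (the fallback
  path for a failed Hessian at an off-manifold neuron is implemented
  and unit-tested with a synthetic failing surface, but exercised only
  there).
- On these surfaces the gradient-extended training space changes the
  clustering but does **not** measurably lower the mean gradient norm
  at the neuron geometries: at low dimension the visited configuration
  cloud is fat, and the off-manifold points produced by cell averaging
  on a symmetric multi-well sit near flat saddle regions rather than on
  steep walls. The force-screening benefit of the extended space is a
  thin-manifold, high-dimensional effect and should not be extrapolated
  from these tests; what the tests do pin down are its contracts
  (doubled training dimension, equal per-component weighting,
  coordinate-block back-transform, degenerate-gradient equivalence).
- CPU-time comparisons between methods are out of scope
  (hardware-dependent); only exact-Hessian budgets are accounted.
- Thermostats, growing/topology-learning gas variants, full
  phase-space Monte Carlo SCIVR and Jacobian-block subspace
  partitioning are out of scope.
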