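# hessgas

Neural-gas Hessian approximation for molecular dynamics, with the two
standard comparators (dynamical Hessian database, compact-finite-difference
Bofill updating), analytic model potentials with exact derivative oracles,
and a semiclassical spectroscopy layer (TA-SCIVR) that consumes the
approximated Hessians.

## The problem

Many MD post-processing methods — instantaneous normal modes, instanton
rates, semiclassical initial-value-representation (SCIVR) spectra — need
the Hessian **H**(t) = ∂²V/∂q² at *every* time step. In ab initio MD each
Hessian costs hours of electronic-structure time, so the practical question
is: given a budget of `m ≪ N_steps` exact Hessians, how accurately can the
full per-step sequence be reconstructed?

Three strategies are implemented behind one interface:

- **Neural gas (`ngas`)** — unsupervised vector quantization
  (Martinetz–Schulten). All trajectory geometries are scaled into the unit
  box (per component, `Q_j = (q_j − m_j)/(M_j − m_j)`), `m` landmark
  "neurons" `Q̃_j` are initialized on the trajectory at fixed strides and
  adapted by annealed rank-weighted updates

  `Q̃_j ← Q̃_j + α(τ)·exp(−K_ij/λ(τ))·(Q_i − Q̃_j)`,

  where `K_ij` ranks neurons by distance from the sampled point and
  `α, λ` decay geometrically over epochs (0.3→0.05 and 30→0.01). After
  freezing, each neuron moves to the centroid of its Voronoi cell, one
  exact Hessian is computed per neuron, and every step borrows its
  neuron's Hessian. A gradient-extended training space
  `(q, ∇V) ∈ [0,1]^{2N}` is available. Budget = number of neurons,
  fixed a priori.
- **Dynamical Hessian database (`dbh`)** — sweep the trajectory in time
  order; reuse a stored Hessian whenever every coordinate of the current
  geometry is within a threshold ρ of a stored entry (nearest hit wins),
  otherwise compute and store. Budget emerges from ρ; a bisection helper
  targets a requested budget within ±5 %.
- **Compact finite difference (`cfd`)** — chain quasi-Newton secant
  updates between periodic exact refreshes:
  SR1, power-symmetric Broyden (PSB), and the Bofill mixture
  `ΔH = (1−λ)ΔH_SR1 + λΔH_PSB` with
  `λ = 1 − (R·ΔX)²/(‖R‖²‖ΔX‖²)`, `R = ΔG − HΔX`.
  Budget = ⌈N_steps/refresh⌉.

Accuracy is measured as the mean absolute error per Hessian element per
step,

`σ_Hess = (1/(N² N_steps)) Σ_k Σ_ij |H_ij(k) − H_ij^approx(k)|`,

against the all-Hessians reference, and spectroscopically: the per-step
Hessians drive the monodromy matrix **M**(t) (d**M**/dt = **A**(t)**M**,
**A** built from −**H**(t)), whose blocks enter the Herman–Kluk prefactor
phase of the time-averaged SCIVR power spectrum

`I(E) ∝ (1/2πT) |∫₀ᵀ dt ⟨χ|p_t q_t⟩ e^{i(S_t + Et + φ_t)}|²`.

Everything runs on built-in analytic surfaces (harmonic, Morse, coupled
Morse, multi-well "quartic tangle") with exact gradients and Hessians, so
budgets and errors are measured against ground truth; trajectories are
generated by a fourth-order symplectic (Forest–Ruth) NVE integrator.

## Worked example

`python examples/03_method_comparison.py` — 50 trajectories of 200 steps
sampled from the Husimi distribution on a 4-dimensional multi-well
surface, 100 exact Hessians for 10,000 steps:

```
method      median sigma_Hess  budget   rel.
ngas                7.982e-07     100   1.00
dbh                 1.238e-06     104   1.55
bofill              1.834e-06     100   2.30
```

`sigma_Hess` is in hartree/bohr² per matrix element (the mean |element|
of the reference Hessians is ~3e-6, so the neural gas is an order of
magnitude below signal at 1 % Hessian cost); `rel.` is each method's
error relative to the neural gas. When trajectories cross and overlap,
landmark clustering reuses geometry revisits that the along-the-path
database and the extrapolating update chain cannot.

The other examples show trajectory generation (`01`), single-trajectory
training and cell statistics (`02`), and TA-SCIVR spectra from
approximated Hessians on a Morse oscillator (`04`).

A thin CLI mirrors the library:

```bash
hessgas generate --surface quartic_tangle_nd --params '{"n_dof": 3}' --out run/
hessgas train-ngas --traj run/traj --neurons 150 --seed 0 --out run/ngas
hessgas bofill     --traj run/traj --refresh 20 --out run/cfd
hessgas evaluate   --ref run/cfd/hessians --approx run/ngas/hessians --out run/report.json
hessgas spectrum   --traj run/traj --hessians run/ngas/hessians --out run/spec
```

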