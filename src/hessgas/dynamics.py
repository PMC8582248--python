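"""Symplectic NVE propagation, normal-mode analysis and initial-condition samplers.

The classical substrate for every Hessian-approximation method: bound-state
constant-energy trajectories on analytic surfaces, integrated with a
fourth-order Forest–Ruth composition, plus the harmonic machinery
(normal modes, zero-point initial conditions, Husimi phase-space sampling)
used to launch them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .surfaces import PotentialSurface

__all__ = [
    "TrajectoryRecord",
    "NormalModeBasis",
    "IntegrationInstabilityError",
    "SaddlePointError",
    "ZeroFrequencyError",
    "integrate_nve",
    "normal_mode_analysis",
    "mc_initial_conditions",
    "sample_husimi_ensemble",
]

# Forest–Ruth 4th-order composition: drift coefficients c_i, kick d_i.
_THETA = 1.0 / (2.0 - 2.0 ** (1.0 / 3.0))
FR_DRIFT = np.array([_THETA / 2, (1 - _THETA) / 2, (1 - _THETA) / 2, _THETA / 2])
FR_KICK = np.array([_THETA, 1 - 2 * _THETA, _THETA, 0.0])


class IntegrationInstabilityError(RuntimeError):
    """Energy diverged during NVE propagation."""

    def __init__(self, step, message):
        self.step = step
        super().__init__(message)


class SaddlePointError(RuntimeError):
    """The located stationary point has significant negative curvature."""


class ZeroFrequencyError(ValueError):
    """An operation requiring bound modes met a (near-)zero frequency."""


@dataclass
class TrajectoryRecord:
    """Time series of a classical trajectory in atomic units.

    ``positions``/``momenta`` are (n_steps, n_dof); ``gradients`` are the
    potential gradients at each stored geometry (optional); ``energies``
    the total energy per step.  ``coordinate_tag`` is ``"cartesian"`` or
    ``"normal_mode"`` (mass-scaled).
    """

    dt: float
    positions: np.ndarray
    momenta: np.ndarray
    energies: np.ndarray
    gradients: Optional[np.ndarray] = None
    coordinate_tag: str = "cartesian"
    masses: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.momenta = np.atleast_2d(np.asarray(self.momenta, dtype=float))
        self.energies = np.atleast_1d(np.asarray(self.energies, dtype=float))
        if self.gradients is not None:
            self.gradients = np.atleast_2d(np.asarray(self.gradients, dtype=float))
        n = self.positions.shape[0]
        if self.momenta.shape != self.positions.shape:
            raise ValueError("positions and momenta shapes differ")
        if self.energies.shape[0] != n:
            raise ValueError("energies length differs from positions")
        if self.gradients is not None and self.gradients.shape != self.positions.shape:
            raise ValueError("gradients shape differs from positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if self.coordinate_tag not in ("cartesian", "normal_mode"):
            raise ValueError(f"unknown coordinate_tag {self.coordinate_tag!r}")
        if self.masses is not None:
            self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dof(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_steps)

    def energy_drift(self) -> float:
        """Max relative deviation of the total energy from its initial value."""
        e0 = self.energies[0]
        scale = abs(e0) if e0 != 0 else 1.0
        return float(np.max(np.abs(self.energies - e0)) / scale)

    def __getitem__(self, sl) -> "TrajectoryRecord":
        if not isinstance(sl, slice):
            raise TypeError("TrajectoryRecord supports slice indexing only")
        return TrajectoryRecord(
            dt=self.dt,
            positions=self.positions[sl],
            momenta=self.momenta[sl],
            energies=self.energies[sl],
            gradients=None if self.gradients is None else self.gradients[sl],
            coordinate_tag=self.coordinate_tag,
            masses=self.masses,
            meta=dict(self.meta),
        )


def integrate_nve(surface: PotentialSurface, q0, p0, dt: float, n_steps: int,
                  divergence_factor: float = 1.0e3) -> TrajectoryRecord:
    """Propagate Hamilton's equations with the 4th-order Forest–Ruth scheme.

    Stores the initial state plus ``n_steps`` updates (``n_steps + 1`` rows).
    Kinetic energy is pᵀ m⁻¹ p / 2; for mass-scaled surfaces all masses are 1.

    Raises :class:`IntegrationInstabilityError` when |E| grows beyond
    ``divergence_factor`` × max(|E₀|, 1e-12).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    q = np.asarray(q0, dtype=float).copy()
    p = np.asarray(p0, dtype=float).copy()
    if q.shape != (surface.n_dof,) or p.shape != (surface.n_dof,):
        raise ValueError("q0/p0 must have length n_dof")
    minv = 1.0 / surface.masses

    nrow = n_steps + 1
    Q = np.empty((nrow, surface.n_dof))
    P = np.empty((nrow, surface.n_dof))
    G = np.empty((nrow, surface.n_dof))
    E = np.empty(nrow)

    def record(i, q, p):
        Q[i], P[i] = q, p
        G[i] = surface.gradient(q)
        E[i] = surface.energy(q) + 0.5 * np.dot(p * minv, p)

    record(0, q, p)
    e_scale = max(abs(E[0]), 1e-12)
    for i in range(1, nrow):
        for c, d in zip(FR_DRIFT, FR_KICK):
            q = q + c * dt * p * minv
            if d != 0.0:
                p = p - d * dt * surface.gradient(q)
        record(i, q, p)
        if abs(E[i]) > divergence_factor * e_scale:
            raise IntegrationInstabilityError(
                i, f"energy diverged at step {i}: E={E[i]:.3e} vs E0={E[0]:.3e}")
    tag = "normal_mode" if np.allclose(surface.masses, 1.0) else "cartesian"
    return TrajectoryRecord(
        dt=dt, positions=Q, momenta=P, energies=E, gradients=G,
        coordinate_tag=tag, masses=surface.masses,
        meta={"surface": surface.name, "surface_params": dict(surface.params)},
    )


@dataclass
class NormalModeBasis:
    """Harmonic normal modes at a located minimum.

    ``mode_matrix`` columns transform mass-weighted Cartesian displacements
    into normal-mode coordinates; ``frequencies`` are all ω_k ≥ 0 sorted
    ascending, with near-zero modes (ω² < zero_tol) excluded from ``n_vib``.
    """

    equilibrium_geometry: np.ndarray
    frequencies: np.ndarray
    mode_matrix: np.ndarray
    n_vib: int
    masses: np.ndarray
    zero_tol: float = 1.0e-10

    @property
    def vib_frequencies(self) -> np.ndarray:
        """Frequencies of the genuine vibrational (nonzero) modes."""
        return self.frequencies[self.frequencies.size - self.n_vib:]

    @property
    def vib_modes(self) -> np.ndarray:
        return self.mode_matrix[:, self.frequencies.size - self.n_vib:]

    def to_normal_modes(self, x: np.ndarray) -> np.ndarray:
        """Mass-scaled normal-mode coordinates of a Cartesian geometry."""
        dx = (np.asarray(x) - self.equilibrium_geometry) * np.sqrt(self.masses)
        return self.mode_matrix.T @ dx

    def from_normal_modes(self, qnm: np.ndarray) -> np.ndarray:
        return self.equilibrium_geometry + (self.mode_matrix @ np.asarray(qnm)) / np.sqrt(self.masses)


def normal_mode_analysis(surface: PotentialSurface, q_guess,
                         zero_tol: float = 1.0e-10,
                         neg_tol: float = 1.0e-8) -> NormalModeBasis:
    """Locate the nearest minimum and diagonalize the mass-weighted Hessian.

    Frequencies are returned ascending.  Raises :class:`SaddlePointError`
    when an eigenvalue is below −neg_tol (negative curvature beyond the
    numerical tolerance of a genuine minimum).
    """
    q_guess = np.asarray(q_guess, dtype=float)
    res = minimize(surface.energy, q_guess, jac=surface.gradient,
                   method="BFGS", options={"gtol": 1e-10, "maxiter": 1000})
    qeq = res.x
    gnorm = np.linalg.norm(surface.gradient(qeq))
    if gnorm > 1e-8:
        raise RuntimeError(f"minimization did not converge: |grad| = {gnorm:.2e}")
    sqm = np.sqrt(surface.masses)
    Hmw = surface.hessian(qeq) / np.outer(sqm, sqm)
    w2, L = np.linalg.eigh(Hmw)
    if w2[0] < -neg_tol:
        raise SaddlePointError(
            f"negative curvature ω² = {w2[0]:.3e} at the stationary point")
    w2 = np.clip(w2, 0.0, None)
    freqs = np.sqrt(w2)
    n_vib = int(np.sum(w2 >= zero_tol))
    return NormalModeBasis(
        equilibrium_geometry=qeq, frequencies=freqs, mode_matrix=L,
        n_vib=n_vib, masses=surface.masses.copy(), zero_tol=zero_tol,
    )


def mc_initial_conditions(basis: NormalModeBasis, target_mode: Optional[int] = None,
                          sign: int = +1):
    """Initial conditions at the minimum with harmonic-level kinetic energy.

    The position is the equilibrium geometry; each vibrational mode k
    receives kinetic energy (n_k + ½) ħ ω_k with n_k = 0 except one quantum
    on ``target_mode`` (an index into the vibrational modes) when given.
    Momenta are along +mode directions unless ``sign`` = −1.

    Returns Cartesian ``(q0, p0)`` (identical to mass-scaled normal-mode
    values when all masses are 1 and the surface is already diagonal).
    """
    nv = basis.n_vib
    quanta = np.zeros(nv)
    if target_mode is not None:
        if not 0 <= target_mode < nv:
            raise IndexError(f"target_mode {target_mode} out of range [0, {nv})")
        quanta[target_mode] = 1.0
    w = basis.vib_frequencies
    p_nm = sign * np.sqrt(2.0 * (quanta + 0.5) * w)   # ½ p² = (n+½) ħ ω
    q0 = basis.equilibrium_geometry.copy()
    p0 = np.sqrt(basis.masses) * (basis.vib_modes @ p_nm)
    return q0, p0


def sample_husimi_ensemble(basis: NormalModeBasis, n_traj: int, seed: int):
    """Draw initial conditions from the coherent-state Husimi distribution.

    Per vibrational mode k the distribution is a Gaussian product with
    Var(q_k) = ħ/(2 ω_k) and Var(p_k) = ħ ω_k / 2, centred at equilibrium
    (ħ = 1).  Zero-frequency modes must already be excluded from the basis
    vibrational block.  Deterministic under ``seed``.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    w = basis.vib_frequencies
    if np.any(w * w < basis.zero_tol):
        raise ZeroFrequencyError(
            "near-zero frequency modes present; exclude them before sampling")
    rng = np.random.default_rng(seed)
    sq = np.sqrt(0.5 / w)
    sp = np.sqrt(0.5 * w)
    out = []
    sqm = np.sqrt(basis.masses)
    for _ in range(n_traj):
        xi = rng.standard_normal(w.size) * sq
        eta = rng.standard_normal(w.size) * sp
        q0 = basis.equilibrium_geometry + (basis.vib_modes @ xi) / sqm
        p0 = sqm * (basis.vib_modes @ eta)
        out.append((q0, p0))
    return out
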