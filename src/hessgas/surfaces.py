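"""Analytic potential-energy surfaces with exact derivative oracles.

Every method in this package is benchmarked against surfaces whose
gradient and Hessian are known in closed form, so that "exact Hessian"
budgets and approximation errors are unambiguous.  All energies are in
hartree, coordinates in bohr (or mass-scaled bohr·sqrt(m_e)), masses in
electron masses; ħ = 1 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "PotentialSurface",
    "SurfaceEvaluationError",
    "fd_hessian",
    "fd_gradient",
    "builtin_surface",
    "BUILTIN_SURFACES",
]


class SurfaceEvaluationError(RuntimeError):
    """Raised when a surface returns a non-finite energy or gradient."""


@dataclass
class PotentialSurface:
    """A potential-energy surface with optional analytic derivatives.

    Parameters
    ----------
    n_dof:
        Number of coordinates.
    energy_at:
        Callable ``q -> float`` (hartree).
    gradient_at:
        Optional callable ``q -> (n_dof,)`` (hartree/bohr).  When absent,
        finite differences of the energy are used.
    hessian_at:
        Optional callable ``q -> (n_dof, n_dof)`` symmetric matrix.  When
        absent, :func:`fd_hessian` supplies the second derivatives.
    masses:
        Per-coordinate masses (a.u.).  Mass-scaled model surfaces use 1.
    fd_displacement:
        Finite-difference step (a.u.), default 1e-3.
    """

    n_dof: int
    energy_at: Callable[[np.ndarray], float]
    gradient_at: Optional[Callable[[np.ndarray], np.ndarray]] = None
    hessian_at: Optional[Callable[[np.ndarray], np.ndarray]] = None
    masses: np.ndarray = None
    fd_displacement: float = 1.0e-3
    name: str = "custom"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_dof < 1:
            raise ValueError("n_dof must be positive")
        if self.masses is None:
            self.masses = np.ones(self.n_dof)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (self.n_dof,) or np.any(self.masses <= 0):
            raise ValueError("masses must be positive and of length n_dof")
        if self.fd_displacement <= 0:
            raise ValueError("fd_displacement must be positive")

    # -- convenience wrappers with validation ---------------------------
    def energy(self, q: np.ndarray) -> float:
        e = float(self.energy_at(np.asarray(q, dtype=float)))
        if not np.isfinite(e):
            raise SurfaceEvaluationError(f"non-finite energy at q={q!r}")
        return e

    def gradient(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        if self.gradient_at is not None:
            g = np.asarray(self.gradient_at(q), dtype=float)
        else:
            g = fd_gradient(self, q)
        if not np.all(np.isfinite(g)):
            bad = int(np.flatnonzero(~np.isfinite(g))[0])
            raise SurfaceEvaluationError(
                f"non-finite gradient component {bad} at q={q!r}")
        return g

    def hessian(self, q: np.ndarray) -> np.ndarray:
        """Exact Hessian: analytic when available, else finite differences."""
        q = np.asarray(q, dtype=float)
        if self.hessian_at is not None:
            h = np.asarray(self.hessian_at(q), dtype=float)
            return 0.5 * (h + h.T)
        return fd_hessian(self, q)


def fd_gradient(surface: PotentialSurface, q: np.ndarray) -> np.ndarray:
    """Second-order central differences of the energy."""
    q = np.asarray(q, dtype=float)
    h = surface.fd_displacement
    g = np.empty(surface.n_dof)
    for k in range(surface.n_dof):
        dq = np.zeros_like(q)
        dq[k] = h
        g[k] = (surface.energy(q + dq) - surface.energy(q - dq)) / (2 * h)
    return g


def fd_hessian(surface: PotentialSurface, q: np.ndarray) -> np.ndarray:
    """Finite-difference Hessian with a fixed displacement (default 1e-3 a.u.).

    Central differences of the analytic gradient when the surface provides
    one; otherwise second differences of the energy.  The result is
    symmetrized.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (surface.n_dof,):
        raise ValueError(f"expected coordinate vector of length {surface.n_dof}")
    h = surface.fd_displacement
    n = surface.n_dof
    H = np.empty((n, n))
    if surface.gradient_at is not None:
        for k in range(n):
            dq = np.zeros(n)
            dq[k] = h
            try:
                gp = surface.gradient(q + dq)
                gm = surface.gradient(q - dq)
            except SurfaceEvaluationError as err:
                raise SurfaceEvaluationError(
                    f"gradient evaluation failed displacing coordinate {k}: {err}"
                ) from err
            H[k] = (gp - gm) / (2 * h)
    else:
        e0 = surface.energy(q)
        for k in range(n):
            dk = np.zeros(n)
            dk[k] = h
            H[k, k] = (surface.energy(q + dk) - 2 * e0 + surface.energy(q - dk)) / h**2
            for l in range(k + 1, n):
                dl = np.zeros(n)
                dl[l] = h
                H[k, l] = H[l, k] = (
                    surface.energy(q + dk + dl)
                    - surface.energy(q + dk - dl)
                    - surface.energy(q - dk + dl)
                    + surface.energy(q - dk - dl)
                ) / (4 * h**2)
    return 0.5 * (H + H.T)


# ----------------------------------------------------------------------
# Built-in model surfaces
# ----------------------------------------------------------------------

def harmonic_nd(omega=(1.0,), masses=None) -> PotentialSurface:
    """Separable harmonic oscillator, V = ½ Σ ω_k² q_k² (mass-scaled)."""
    omega = np.atleast_1d(np.asarray(omega, dtype=float))
    n = omega.size
    w2 = omega**2
    H0 = np.diag(w2)
    return PotentialSurface(
        n_dof=n,
        energy_at=lambda q: 0.5 * float(np.dot(w2, np.square(q))),
        gradient_at=lambda q: w2 * q,
        hessian_at=lambda q: H0.copy(),
        masses=masses,
        name="harmonic_nd",
        params={"omega": omega.tolist()},
    )


def morse_1d(D=0.176, a=1.02, mass=1.0) -> PotentialSurface:
    """1D Morse oscillator, V(x) = D (1 − e^{−a x})².

    Defaults are HF-like well depth/width; pass ``mass`` for a physical
    reduced mass (the harmonic frequency is ω₀ = a √(2D/m)).
    """
    def energy(q):
        u = 1.0 - np.exp(-a * q[0])
        return D * u * u

    def grad(q):
        e = np.exp(-a * q[0])
        return np.array([2.0 * D * a * e * (1.0 - e)])

    def hess(q):
        e = np.exp(-a * q[0])
        return np.array([[2.0 * D * a * a * e * (2.0 * e - 1.0)]])

    return PotentialSurface(
        n_dof=1, energy_at=energy, gradient_at=grad, hessian_at=hess,
        masses=[mass], name="morse_1d", params={"D": D, "a": a, "mass": mass},
    )


def coupled_morse_2d(D1=0.176, a1=0.02, D2=0.176, a2=0.025, lam=0.0,
                     masses=None) -> PotentialSurface:
    """Two Morse oscillators with a Morse-type bilinear coupling.

    V = D1 u1² + D2 u2² + λ u1 u2 with u_k = 1 − e^{−a_k q_k}; the
    off-diagonal Hessian element λ a1 a2 e^{−a1 q1} e^{−a2 q2} is
    position-dependent and vanishes identically when λ = 0.
    Default widths give molecular-scale frequencies in mass-scaled
    coordinates (ω₀ ≈ a √(2D)).
    """
    def parts(q):
        e1, e2 = np.exp(-a1 * q[0]), np.exp(-a2 * q[1])
        return e1, e2, 1.0 - e1, 1.0 - e2

    def energy(q):
        e1, e2, u1, u2 = parts(q)
        return D1 * u1 * u1 + D2 * u2 * u2 + lam * u1 * u2

    def grad(q):
        e1, e2, u1, u2 = parts(q)
        return np.array([
            a1 * e1 * (2.0 * D1 * u1 + lam * u2),
            a2 * e2 * (2.0 * D2 * u2 + lam * u1),
        ])

    def hess(q):
        e1, e2, u1, u2 = parts(q)
        # u_k' = a_k e_k, u_k'' = −a_k² e_k; V_kk = 2 D_k (u_k'² + u_k u_k'') + λ u_other u_k''
        u1p, u1pp = a1 * e1, -a1 * a1 * e1
        u2p, u2pp = a2 * e2, -a2 * a2 * e2
        h11 = 2.0 * D1 * (u1p * u1p + u1 * u1pp) + lam * u2 * u1pp
        h22 = 2.0 * D2 * (u2p * u2p + u2 * u2pp) + lam * u1 * u2pp
        h12 = lam * u1p * u2p
        return np.array([[h11, h12], [h12, h22]])

    return PotentialSurface(
        n_dof=2, energy_at=energy, gradient_at=grad, hessian_at=hess,
        masses=masses, name="coupled_morse_2d",
        params={"D1": D1, "a1": a1, "D2": D2, "a2": a2, "lam": lam},
    )


def quartic_tangle_nd(n_dof=4, b=2.2e-9, c=15.0, g=2.0e-10,
                      detune=0.1) -> PotentialSurface:
    """Coupled double-well quartic surface with 2^n minima.

    V = Σ_k b_k (q_k² − c²)² + g Σ_{k<l} q_k² q_l²,  b_k = b (1 + detune·k).

    Designed (in mass-scaled coordinates, unit masses) so that the well
    frequency ω_k = √(8 b_k) c ≈ 2e-3 a.u. is molecular-scale, the barrier
    b c⁴ ≈ 1.1e-4 hartree sits well below the per-mode zero-point energy
    ω/2 ≈ 1e-3 hartree, and the pairwise couplings make the Hessian
    position-dependent while staying weak enough not to reshape the well
    structure.  Trajectories started near a minimum with
    zero-point-scale energy therefore wander between wells and ensembles
    of them cross — the regime where landmark clustering must outperform
    naive along-the-trajectory reuse.
    """
    bk = b * (1.0 + detune * np.arange(n_dof))
    c2 = c * c

    def energy(q):
        q = np.asarray(q, dtype=float)
        q2 = q * q
        v = float(np.dot(bk, (q2 - c2) ** 2))
        s = q2.sum()
        v += 0.5 * g * (s * s - np.dot(q2, q2))  # Σ_{k<l} q_k² q_l²
        return v

    def grad(q):
        q = np.asarray(q, dtype=float)
        q2 = q * q
        s = q2.sum()
        return 4.0 * bk * q * (q2 - c2) + 2.0 * g * q * (s - q2)

    def hess(q):
        q = np.asarray(q, dtype=float)
        q2 = q * q
        s = q2.sum()
        H = 4.0 * g * np.outer(q, q)
        np.fill_diagonal(H, 4.0 * bk * (3.0 * q2 - c2) + 2.0 * g * (s - q2))
        return H

    return PotentialSurface(
        n_dof=n_dof, energy_at=energy, gradient_at=grad, hessian_at=hess,
        name="quartic_tangle_nd",
        params={"n_dof": n_dof, "b": b, "c": c, "g": g, "detune": detune},
    )


BUILTIN_SURFACES = {
    "harmonic_nd": harmonic_nd,
    "morse_1d": morse_1d,
    "coupled_morse_2d": coupled_morse_2d,
    "quartic_tangle_nd": quartic_tangle_nd,
}


def builtin_surface(name: str, **params) -> PotentialSurface:
    """Catalog lookup for the built-in analytic surfaces."""
    try:
        factory = BUILTIN_SURFACES[name]
    except KeyError:
        raise KeyError(
            f"unknown surface {name!r}; available: {sorted(BUILTIN_SURFACES)}"
        ) from None
    return factory(**params)
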