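"""Semiclassical vibrational spectroscopy from approximated Hessians.

The monodromy (stability) matrix M(t) is propagated alongside a classical
trajectory from the per-step Hessian sequence; its blocks feed the
Herman–Kluk (HHKK) prefactor phase, and the time-averaged semiclassical
initial-value-representation (TA-SCIVR) power spectrum is assembled in
its few-trajectory (multiple-coherent-states) form

    I(E) ∝ (1/2πT) | ∫₀ᵀ dt ⟨χ| p_t q_t⟩ exp{i [S_t + E t + φ_t]} |²,

with S_t the instantaneous classical action, φ_t the continuously
unwound prefactor phase, and |χ⟩ an (optionally ±-momentum combined)
coherent reference state.  Everything is in mass-scaled normal-mode
coordinates and atomic units, ħ = 1.

The coherent-state width matrix γ is diagonal with the system's harmonic
frequencies.  Convention used here (pinned by the exact harmonic limit):

    ⟨x|p q⟩ = (det γ/πᴺ)^¼ exp[−(x−q)ᵀγ(x−q)/2 + i pᵀ(x−q)]
    C_t = √det{½(M_qq + γ⁻¹ M_pp γ + i γ⁻¹ M_pq − i M_qp γ)}
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import cumulative_simpson
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .dynamics import TrajectoryRecord, FR_DRIFT, FR_KICK
from .surfaces import PotentialSurface

HARTREE_TO_CM1 = 219474.6313632  # CODATA E_h / (h c) in cm^-1

__all__ = [
    "MonodromyMatrix",
    "CoherentStateParams",
    "SpectrumResult",
    "SubspaceDecomposition",
    "propagate_monodromy",
    "hhkk_prefactor_phase",
    "coherent_overlap",
    "ta_sivr_spectrum",
    "quasi_classical_spectrum",
    "dc_project_potential",
    "coarse_grain_subspaces",
    "HARTREE_TO_CM1",
]


@dataclass
class MonodromyMatrix:
    """2N×2N stability matrix in (p, q) block order.

    ``matrix`` rows/columns are ordered (δp, δq); blocks are
    M_pp = ∂p_t/∂p_0, M_pq = ∂p_t/∂q_0, M_qp = ∂q_t/∂p_0, M_qq = ∂q_t/∂q_0.
    """

    matrix: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0] // 2

    @property
    def M_pp(self) -> np.ndarray:
        return self.matrix[: self.n, : self.n]

    @property
    def M_pq(self) -> np.ndarray:
        return self.matrix[: self.n, self.n:]

    @property
    def M_qp(self) -> np.ndarray:
        return self.matrix[self.n:, : self.n]

    @property
    def M_qq(self) -> np.ndarray:
        return self.matrix[self.n:, self.n:]

    def symplecticity_deviation(self) -> float:
        """|det(MᵀM) − 1|, the accuracy monitor."""
        return abs(float(np.linalg.det(self.matrix.T @ self.matrix)) - 1.0)

    @classmethod
    def identity(cls, n: int) -> "MonodromyMatrix":
        return cls(matrix=np.eye(2 * n))


@dataclass
class CoherentStateParams:
    """Diagonal width matrix γ of harmonic frequencies (a.u.)."""

    gamma: np.ndarray

    def __post_init__(self):
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if np.any(self.gamma <= 0):
            raise ValueError("gamma must be strictly positive")

    @property
    def n(self) -> int:
        return self.gamma.size


@dataclass
class SpectrumResult:
    """Power spectrum on a strictly increasing energy grid (a.u.)."""

    energy_grid: np.ndarray
    intensity: np.ndarray
    normalization: str = "arbitrary"

    def __post_init__(self):
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.energy_grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < -1e-300):
            raise ValueError("intensities must be finite and nonnegative")

    @property
    def energy_cm1(self) -> np.ndarray:
        return self.energy_grid * HARTREE_TO_CM1

    def peak_positions(self, min_rel_height: float = 1e-3) -> np.ndarray:
        """Local maxima above ``min_rel_height`` × global maximum."""
        y = self.intensity
        top = y.max()
        idx = np.flatnonzero(
            (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]) & (y[1:-1] >= min_rel_height * top)
        ) + 1
        return self.energy_grid[idx]


@dataclass
class SubspaceDecomposition:
    """Disjoint vibrational-mode index sets covering 0..N_vib−1."""

    subspaces: List[np.ndarray]

    def __post_init__(self):
        cover = np.concatenate([np.asarray(s) for s in self.subspaces])
        if np.unique(cover).size != cover.size:
            raise ValueError("subspaces must be disjoint")

    @property
    def n_modes(self) -> int:
        return sum(len(s) for s in self.subspaces)


# ----------------------------------------------------------------------
# Monodromy propagation
# ----------------------------------------------------------------------

def propagate_monodromy(hessian_sequence: np.ndarray, dt: float):
    """Integrate dM/dt = A(t) M, A = [[0, −H(t)], [I, 0]], from identity.

    Uses the same fourth-order symplectic composition as the trajectory
    integrator, with the Hessian held at its step value within each step;
    each kick/drift is a unit-determinant shear, so the symplectic
    monitor det(MᵀM) stays at 1 to round-off regardless of how the
    Hessians were approximated.

    Returns ``(monodromies, deviations)``: a list of
    :class:`MonodromyMatrix` (one per step, starting at the identity) and
    the per-step |det(MᵀM) − 1| monitor.
    """
    H = np.asarray(hessian_sequence, dtype=float)
    if H.ndim != 3 or H.shape[1] != H.shape[2]:
        raise ValueError("hessian_sequence must be (n_steps, n, n)")
    n = H.shape[1]
    Mp = np.hstack([np.eye(n), np.zeros((n, n))])   # (δp rows)
    Mq = np.hstack([np.zeros((n, n)), np.eye(n)])   # (δq rows)
    out = [MonodromyMatrix(matrix=np.vstack([Mp, Mq]).copy())]
    for k in range(1, H.shape[0]):
        Hk = H[k - 1]
        for c, d in zip(FR_DRIFT, FR_KICK):
            Mq = Mq + (c * dt) * Mp
            if d != 0.0:
                Mp = Mp - (d * dt) * (Hk @ Mq)
        out.append(MonodromyMatrix(matrix=np.vstack([Mp, Mq]).copy()))
    dev = np.array([m.symplecticity_deviation() for m in out])
    return out, dev


def hhkk_prefactor_phase(monodromies: Sequence[MonodromyMatrix],
                         gamma: CoherentStateParams,
                         caustic_tol: float = 1e-12):
    """Continuous phase φ_t of the HHKK prefactor along a trajectory.

    Evaluates the determinant combination
    ½(M_qq + γ⁻¹ M_pp γ + i γ⁻¹ M_pq − i M_qp γ) per step, unwinds its
    argument across steps (branch tracking), and returns φ_t = ½·arg,
    together with the determinant moduli and the flagged caustic steps
    (vanishing modulus; unwinding is preserved through them).

    Returns ``(phi, moduli, caustic_steps)``.
    """
    g = gamma.gamma
    ginv = 1.0 / g
    dets = np.empty(len(monodromies), dtype=complex)
    for k, M in enumerate(monodromies):
        block = 0.5 * (
            M.M_qq
            + ginv[:, None] * M.M_pp * g[None, :]
            + 1j * ginv[:, None] * M.M_pq
            - 1j * M.M_qp * g[None, :]
        )
        dets[k] = np.linalg.det(block)
    moduli = np.abs(dets)
    caustics = np.flatnonzero(moduli < caustic_tol)
    if caustics.size:
        warnings.warn(f"prefactor determinant vanished at steps {caustics.tolist()}")
    args = np.angle(dets)
    phi = 0.5 * np.unwrap(args)
    phi -= phi[0]
    return phi, moduli, caustics


# ----------------------------------------------------------------------
# Coherent states and spectra
# ----------------------------------------------------------------------

def coherent_overlap(p1, q1, p2, q2, gamma: CoherentStateParams) -> complex:
    """⟨p1 q1 | p2 q2⟩ for common diagonal width γ (ħ = 1)."""
    g = gamma.gamma
    dq = np.asarray(q2, float) - np.asarray(q1, float)
    dp = np.asarray(p2, float) - np.asarray(p1, float)
    ex = (-0.25 * np.dot(g, dq * dq)
          - 0.25 * np.dot(dp * dp, 1.0 / g)
          - 0.5j * np.dot(np.asarray(p1, float) + np.asarray(p2, float), dq))
    return np.exp(ex)


def _overlap_series(p_t, q_t, reference, gamma):
    """⟨χ|p_t q_t⟩ for every step; χ = Σ c_k |p_ref_k q_ref_k⟩."""
    g = gamma.gamma
    n_t = p_t.shape[0]
    out = np.zeros(n_t, dtype=complex)
    norm2 = 0.0
    for ck, pr, qr in reference:
        dq = q_t - qr[None, :]
        dp = p_t - pr[None, :]
        ex = (-0.25 * (dq * dq) @ g
              - 0.25 * (dp * dp) @ (1.0 / g)
              - 0.5j * ((p_t + pr[None, :]) * dq).sum(axis=1))
        out += np.conj(ck) * np.exp(ex)
    for ck, pk, qk in reference:
        for cl, pl, ql in reference:
            norm2 += (np.conj(ck) * cl * coherent_overlap(pk, qk, pl, ql, gamma)).real
    if norm2 > 0:
        out /= np.sqrt(norm2)
    return out


def classical_action(trajectory: TrajectoryRecord) -> np.ndarray:
    """Cumulative action S_t = ∫ (pᵀm⁻¹p − E) dt' along the stored steps."""
    m = trajectory.masses if trajectory.masses is not None else 1.0
    ke2 = np.einsum("ij,ij->i", trajectory.momenta / m, trajectory.momenta)
    lagrangian = ke2 - trajectory.energies
    return cumulative_simpson(lagrangian, dx=trajectory.dt, initial=0.0)


def ta_sivr_spectrum(trajectory: TrajectoryRecord,
                     hessian_sequence: np.ndarray,
                     gamma: CoherentStateParams,
                     energy_grid: Optional[np.ndarray] = None,
                     reference: Optional[Sequence[Tuple[complex, np.ndarray, np.ndarray]]] = None,
                     mode_signs: Optional[Sequence[Sequence[int]]] = None,
                     ) -> SpectrumResult:
    """Single/few-trajectory TA-SCIVR power spectrum.

    ``reference`` is a list of ``(coeff, p_ref, q_ref)`` coherent-state
    terms defining |χ⟩; by default χ is the coherent state at the
    trajectory's initial phase-space point.  ``mode_signs`` instead builds
    the ±-momentum combinations for mode filtering: each entry is a sign
    pattern ε ∈ {±1}^N and χ ∝ Σ_patterns |ε∘p₀, q₀⟩ with unit
    coefficients (pass explicit coefficients through ``reference`` for
    anything fancier).

    Energies are absolute (the zero-point level is visible).  A grid
    coarser than the Fourier-limited width 2π/T triggers a warning.
    """
    if trajectory.n_steps == 0:
        grid = energy_grid if energy_grid is not None else np.linspace(0, 1, 2)
        return SpectrumResult(energy_grid=grid, intensity=np.zeros(len(grid)))
    p_t, q_t = trajectory.momenta, trajectory.positions
    p0, q0 = p_t[0], q_t[0]
    if reference is None:
        if mode_signs is not None:
            reference = [(1.0 + 0j, np.asarray(s, float) * p0, q0)
                         for s in mode_signs]
        else:
            reference = [(1.0 + 0j, p0, q0)]

    T = trajectory.dt * (trajectory.n_steps - 1)
    if energy_grid is None:
        e_top = 1.2 * np.sum(0.5 * gamma.gamma) * 3.0
        energy_grid = np.linspace(0.0, max(e_top, 1e-6), 2048)
    energy_grid = np.asarray(energy_grid, dtype=float)
    if T > 0:
        fourier_width = 2.0 * np.pi / T
        spacing = np.max(np.diff(energy_grid))
        if spacing > fourier_width:
            warnings.warn(
                f"energy grid spacing {spacing:.3e} exceeds the "
                f"Fourier-limited width {fourier_width:.3e} a.u.")

    monos, _ = propagate_monodromy(hessian_sequence, trajectory.dt)
    phi, _, _ = hhkk_prefactor_phase(monos, gamma)
    S = classical_action(trajectory)
    chi = _overlap_series(p_t, q_t, reference, gamma)
    core = chi * np.exp(1j * (S + phi))

    t = trajectory.times
    w = np.full(t.size, trajectory.dt)
    w[0] = w[-1] = 0.5 * trajectory.dt                  # trapezoid in time
    phases = np.exp(1j * np.outer(energy_grid, t))
    amp = phases @ (w * core)
    intensity = np.abs(amp) ** 2 / (2.0 * np.pi * max(T, trajectory.dt))
    return SpectrumResult(energy_grid=energy_grid, intensity=intensity)


def quasi_classical_spectrum(trajectory: TrajectoryRecord,
                             energy_grid: Optional[np.ndarray] = None
                             ) -> SpectrumResult:
    """Fourier power spectrum of the velocity autocorrelation (no damping).

    Computed as Σ_k |∫ v_k(t) e^{iEt} dt|², the Wiener–Khinchin equivalent
    of transforming the velocity–velocity correlation function; no
    artificial exponential decay is applied.
    """
    if trajectory.momenta is None:
        raise ValueError("momenta required")
    m = trajectory.masses if trajectory.masses is not None else 1.0
    v = trajectory.momenta / m
    t = trajectory.times
    T = t[-1] - t[0] if t.size > 1 else trajectory.dt
    if energy_grid is None:
        nyq = np.pi / trajectory.dt
        energy_grid = np.linspace(0.0, nyq, 2048)
    energy_grid = np.asarray(energy_grid, dtype=float)
    w = np.full(t.size, trajectory.dt)
    if t.size > 1:
        w[0] = w[-1] = 0.5 * trajectory.dt
    phases = np.exp(1j * np.outer(energy_grid, t))
    amps = phases @ (w[:, None] * v)
    intensity = (np.abs(amps) ** 2).sum(axis=1) / (2.0 * np.pi * max(T, trajectory.dt))
    return SpectrumResult(energy_grid=energy_grid, intensity=intensity)


def dc_project_potential(surface: PotentialSurface,
                         subspace: Sequence[int],
                         full_state: np.ndarray,
                         equilibrium: np.ndarray) -> float:
    """Divide-and-conquer potential projection for a mode subspace.

    Returns V(q̃_t, q_t^{rest}) − V(q̃_eq, q_t^{rest}): the full potential
    minus the potential with the subspace coordinates clamped at their
    equilibrium values.
    """
    subspace = np.asarray(subspace, dtype=int)
    if subspace.size == 0:
        raise ValueError("subspace must be nonempty")
    q = np.asarray(full_state, dtype=float)
    clamped = q.copy()
    clamped[subspace] = np.asarray(equilibrium, dtype=float)[subspace]
    return surface.energy(q) - surface.energy(clamped)


def coarse_grain_subspaces(time_averaged_hessian: np.ndarray,
                           threshold: float = 8.0e-6) -> SubspaceDecomposition:
    """Partition modes by thresholding the time-averaged Hessian.

    Elements with |H_ij| < threshold (default 8.0e-6 a.u.) are zeroed;
    modes i ≠ j remain connected iff their element survives, and the
    connected components of that adjacency are the vibrational subspaces.
    """
    H = np.asarray(time_averaged_hessian, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("expected a square matrix")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    adj = (np.abs(H) >= threshold).astype(int)
    np.fill_diagonal(adj, 1)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    subspaces = [np.flatnonzero(labels == c) for c in range(n_comp)]
    subspaces.sort(key=lambda s: int(s[0]))
    return SubspaceDecomposition(subspaces=subspaces)
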