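"""Shared fixtures: small surfaces, bases and trajectories, built once."""

import numpy as np
import pytest

import hessgas as hg


@pytest.fixture(scope="session")
def quartic3():
    """3D quartic-tangle surface with its minimum basis and a 1000-step run."""
    surf = hg.builtin_surface("quartic_tangle_nd", n_dof=3)
    basis = hg.normal_mode_analysis(surf, np.full(3, 15.0))
    q0, p0 = hg.mc_initial_conditions(basis)
    traj = hg.integrate_nve(surf, q0, p0, 10.0, 999)[:1000]
    return surf, basis, traj


@pytest.fixture(scope="session")
def quartic4_ensemble():
    """4D quartic tangle with a 50-trajectory Husimi ensemble (200 steps each)."""
    surf = hg.builtin_surface("quartic_tangle_nd", n_dof=4)
    basis = hg.normal_mode_analysis(surf, np.full(4, 15.0))
    ens = hg.sample_husimi_ensemble(basis, 50, seed=1)
    trajs = [hg.integrate_nve(surf, q, p, 10.0, 199) for q, p in ens]
    return surf, basis, trajs


@pytest.fixture(scope="session")
def harmonic6_traj():
    """6D harmonic surface with molecular-scale frequencies and a 600-step run."""
    surf = hg.builtin_surface("harmonic_nd", omega=np.linspace(1e-3, 3e-3, 6))
    basis = hg.normal_mode_analysis(surf, np.zeros(6))
    q0, p0 = hg.mc_initial_conditions(basis)
    traj = hg.integrate_nve(surf, q0, p0, 10.0, 599)[:600]
    return surf, basis, traj


@pytest.fixture(scope="session")
def morse_hf():
    """Mass-scaled HF-like Morse oscillator (D=0.176, a=1.02, m=1744 a.u.)."""
    m = 1744.0
    surf = hg.builtin_surface("morse_1d", D=0.176, a=1.02 / np.sqrt(m), mass=1.0)
    basis = hg.normal_mode_analysis(surf, [0.1])
    return surf, basis
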