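"""Compact-finite-difference Hessian updating along a trajectory.

Quasi-Newton secant updates chained between periodic exact refreshes:
symmetric rank-one (SR1), power-symmetric Broyden (PSB), and the Bofill
combination ΔH = (1−λ)ΔH_SR1 + λΔH_PSB with

    λ = 1 − (R·ΔX)² / (‖R‖² ‖ΔX‖²),      R = ΔG − H ΔX,

so that λ → 1 suppresses the SR1 term exactly when its denominator R·ΔX
degenerates (R nearly orthogonal to ΔX).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .dynamics import TrajectoryRecord
from .surfaces import PotentialSurface

__all__ = ["UpdateState", "bofill_delta", "bofill_lambda", "cfd_run"]

_SCHEMES = ("sr1", "psb", "bofill")


@dataclass
class UpdateState:
    """Latest geometry/gradient/Hessian information for chained updates."""

    x_current: np.ndarray
    g_current: np.ndarray
    h_current: np.ndarray
    scheme: str = "bofill"
    lambda_fixed: Optional[float] = None

    def __post_init__(self):
        self.x_current = np.asarray(self.x_current, dtype=float)
        self.g_current = np.asarray(self.g_current, dtype=float)
        h = np.asarray(self.h_current, dtype=float)
        self.h_current = 0.5 * (h + h.T)
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}")


def bofill_lambda(R: np.ndarray, dX: np.ndarray) -> float:
    """Bofill mixing weight, clipped to [0, 1]."""
    rr = float(np.dot(R, R))
    xx = float(np.dot(dX, dX))
    if rr == 0.0 or xx == 0.0:
        return 1.0
    lam = 1.0 - float(np.dot(R, dX)) ** 2 / (rr * xx)
    return min(max(lam, 0.0), 1.0)


def bofill_delta(state: UpdateState, x_new: np.ndarray,
                 g_new: np.ndarray) -> np.ndarray:
    """Secant update ΔH for the step (x, g) → (x_new, g_new).

    SR1 and PSB both satisfy (H+ΔH)ΔX = ΔG exactly; so does any λ mixture.
    A zero-length step is degenerate and returns ΔH = 0 with a warning.
    """
    dX = np.asarray(x_new, dtype=float) - state.x_current
    dG = np.asarray(g_new, dtype=float) - state.g_current
    n = dX.size
    if np.dot(dX, dX) == 0.0:
        warnings.warn("degenerate update step (ΔX = 0); returning ΔH = 0")
        return np.zeros((n, n))
    R = dG - state.h_current @ dX
    rr = float(np.dot(R, R))
    if rr == 0.0:
        return np.zeros((n, n))
    xx = float(np.dot(dX, dX))
    rx = float(np.dot(R, dX))

    if state.lambda_fixed is not None:
        lam = float(state.lambda_fixed)
    elif state.scheme == "sr1":
        lam = 0.0
    elif state.scheme == "psb":
        lam = 1.0
    else:
        lam = bofill_lambda(R, dX)

    dH = np.zeros((n, n))
    if lam < 1.0:
        if rx == 0.0:
            # SR1 singular; fall back entirely on PSB.
            lam = 1.0
        else:
            dH += (1.0 - lam) * np.outer(R, R) / rx
    if lam > 0.0:
        psb = (np.outer(R, dX) + np.outer(dX, R)) / xx \
            - (rx / (xx * xx)) * np.outer(dX, dX)
        dH += lam * psb
    return 0.5 * (dH + dH.T)


def cfd_run(trajectory: TrajectoryRecord, surface: PotentialSurface,
            refresh_every: int, scheme: str = "bofill",
            lambda_fixed: Optional[float] = None):
    """Chain updates along a trajectory with periodic exact refreshes.

    Step 0 and every ``refresh_every``-th step take an exact Hessian
    (counted in the budget); intermediate steps chain secant updates from
    the most recent state.  Returns ``(hessian_sequence, budget)`` with
    budget = ceil(n_steps / refresh_every).
    """
    if refresh_every < 1:
        raise ValueError("refresh_every must be >= 1")
    if trajectory.gradients is None:
        raise ValueError("cfd_run requires trajectory gradients")
    n = trajectory.n_steps
    seq = np.empty((n, trajectory.n_dof, trajectory.n_dof))
    budget = 0
    state = None
    for k in range(n):
        x, g = trajectory.positions[k], trajectory.gradients[k]
        if k % refresh_every == 0:
            H = surface.hessian(x)
            budget += 1
        else:
            dH = bofill_delta(state, x, g)
            H = state.h_current + dH
        H = 0.5 * (H + H.T)
        seq[k] = H
        state = UpdateState(x_current=x, g_current=g, h_current=H,
                            scheme=scheme, lambda_fixed=lambda_fixed)
    assert budget == -(-n // refresh_every)
    return seq, budget
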