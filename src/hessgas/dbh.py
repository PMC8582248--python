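"""Dynamical Hessian database: threshold-based reuse of stored Hessians.

A trajectory is swept in time order; a step whose geometry lies within a
threshold ρ of a stored entry reuses that entry's Hessian, otherwise the
exact Hessian is computed and appended.  Two closeness criteria are
supported: a per-component test (every |Δx_k| < ρ, the stricter one, used
by default) and a mean-absolute-difference test.  Distances are taken in
the trajectory's native coordinates, so ρ is system-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .dynamics import TrajectoryRecord
from .surfaces import PotentialSurface

__all__ = ["HessianDatabase", "dbh_query", "dbh_run", "rho_for_budget"]

_CRITERIA = ("eq4_mean", "eq5_per_component")


@dataclass
class HessianDatabase:
    """Ordered geometry → Hessian entries with a reuse threshold ρ."""

    rho: float
    criterion: str = "eq5_per_component"
    geometries: List[np.ndarray] = field(default_factory=list)
    hessians: List[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.criterion not in _CRITERIA:
            raise ValueError(f"criterion must be one of {_CRITERIA}")

    def __len__(self) -> int:
        return len(self.geometries)

    def append(self, geometry: np.ndarray, hessian: np.ndarray):
        hessian = np.asarray(hessian, dtype=float)
        self.geometries.append(np.asarray(geometry, dtype=float).copy())
        self.hessians.append(0.5 * (hessian + hessian.T))

    def _geometry_array(self) -> np.ndarray:
        return np.vstack(self.geometries) if self.geometries else np.empty((0, 0))


def dbh_query(db: HessianDatabase, x: np.ndarray) -> Optional[Tuple[np.ndarray, int]]:
    """Look up a geometry; returns ``(hessian, entry_index)`` or None on miss.

    Per-component criterion: a hit needs |x_k − x'_k| < ρ strictly for
    every k (evaluated mode after mode with early termination); among
    multiple hits the entry minimizing max_k |x_k − x'_k| wins.  Mean
    criterion: hit when the mean absolute component difference < ρ, best
    hit minimizes that mean.
    """
    if len(db) == 0:
        return None
    x = np.asarray(x, dtype=float)
    if x.shape != db.geometries[0].shape:
        raise ValueError(
            f"dimension mismatch: query {x.shape} vs entries {db.geometries[0].shape}")
    rho = db.rho
    diffs = np.abs(db._geometry_array() - x)
    if db.criterion == "eq5_per_component":
        # Equivalent to a mode-after-mode scan with early termination:
        # an entry is a hit only if every component difference is < rho.
        scores = diffs.max(axis=1)
        hits = np.flatnonzero(np.all(diffs < rho, axis=1))
    else:
        scores = diffs.mean(axis=1)
        hits = np.flatnonzero(scores < rho)
    if hits.size == 0:
        return None
    best = int(hits[np.argmin(scores[hits])])
    return db.hessians[best], best


def dbh_run(trajectory: TrajectoryRecord, surface: PotentialSurface,
            rho: float, criterion: str = "eq5_per_component",
            db: Optional[HessianDatabase] = None):
    """Sweep a trajectory, growing the database on misses.

    Returns ``(hessian_sequence, db, budget)`` where budget counts the
    exact Hessian evaluations performed during this run.
    """
    if db is None:
        db = HessianDatabase(rho=rho, criterion=criterion)
    budget = 0
    seq = np.empty((trajectory.n_steps, trajectory.n_dof, trajectory.n_dof))
    for k, x in enumerate(trajectory.positions):
        hit = dbh_query(db, x) if len(db) else None
        if hit is not None:
            seq[k] = hit[0]
        else:
            try:
                H = surface.hessian(x)
            except Exception as err:
                raise RuntimeError(f"surface failed at step {k}: {err}") from err
            db.append(x, H)
            budget += 1
            seq[k] = db.hessians[-1]
    return seq, db, budget


def rho_for_budget(trajectory: TrajectoryRecord, surface: PotentialSurface,
                   target_budget: int, criterion: str = "eq5_per_component",
                   rel_tol: float = 0.05, max_iter: int = 60):
    """Bisect on ρ until the realized budget is within ±rel_tol of target.

    The budget is non-increasing in ρ but integer-valued, so an exact
    match may be unattainable; the closest bracketing ρ is returned with
    its realized budget.  Returns ``(rho, realized_budget)``.
    """
    if target_budget < 1:
        raise ValueError("target_budget must be >= 1")
    span = trajectory.positions.max(axis=0) - trajectory.positions.min(axis=0)
    lo = 1e-12 * max(float(span.max()), 1.0)   # budget(lo) ~ n_steps
    hi = 4.0 * float(span.max()) + 1e-9        # budget(hi) = 1

    def budget_at(rho):
        _, _, b = dbh_run(trajectory, surface, rho, criterion)
        return b

    b_lo, b_hi = budget_at(lo), budget_at(hi)
    if target_budget >= b_lo:
        return lo, b_lo
    if target_budget <= b_hi:
        return hi, b_hi
    best = (lo, b_lo)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        b = budget_at(mid)
        if abs(b - target_budget) < abs(best[1] - target_budget):
            best = (mid, b)
        if abs(b - target_budget) <= rel_tol * target_budget:
            return mid, b
        if b > target_budget:
            lo = mid
        else:
            hi = mid
    return best
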