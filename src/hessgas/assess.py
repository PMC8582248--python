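"""Hessian-approximation error metric and matched-budget method comparison.

The accuracy metric is the mean absolute error per Hessian element per
step,

    σ_Hess = (1 / (N² N_steps)) Σ_k Σ_ij |H_ij(k) − H_ij^approx(k)|,

evaluated in Cartesian coordinates (for mass-scaled normal-mode
trajectories the basis transform is applied first when a normal-mode
basis is supplied).  The comparison harness runs the neural-gas, database
and compact-finite-difference methods against the all-Hessians reference
at a matched exact-Hessian budget and aggregates over seeds by median.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Union

import numpy as np

from .dynamics import TrajectoryRecord, NormalModeBasis
from .surfaces import PotentialSurface
from .ngas import GasSchedule, ngas_run
from .dbh import dbh_run, rho_for_budget
from .cfd import cfd_run

__all__ = ["ApproximationReport", "sigma_hess", "compare_methods",
           "exact_hessian_sequence", "hessians_to_cartesian",
           "concatenate_trajectories"]


@dataclass
class ApproximationReport:
    """σ_Hess, its per-step decomposition, and the exact-Hessian budget."""

    method: str
    sigma_hess: float
    per_step_mae: np.ndarray
    budget: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.per_step_mae = np.asarray(self.per_step_mae, dtype=float)

    def to_json(self) -> str:
        d = asdict(self)
        d["per_step_mae"] = self.per_step_mae.tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ApproximationReport":
        d = json.loads(text)
        return cls(**d)


def sigma_hess(reference: np.ndarray, approx: np.ndarray,
               method: str = "unknown", budget: int = 0,
               metadata: Optional[dict] = None) -> ApproximationReport:
    """Mean absolute error of Hessian elements across a step sequence."""
    ref = np.asarray(reference, dtype=float)
    app = np.asarray(approx, dtype=float)
    if ref.shape != app.shape or ref.ndim != 3 or ref.shape[1] != ref.shape[2]:
        raise ValueError(
            f"shape mismatch: reference {ref.shape} vs approx {app.shape}")
    per_step = np.abs(ref - app).mean(axis=(1, 2))
    return ApproximationReport(
        method=method, sigma_hess=float(per_step.mean()),
        per_step_mae=per_step, budget=budget, metadata=metadata or {})


def exact_hessian_sequence(trajectory: TrajectoryRecord,
                           surface: PotentialSurface) -> np.ndarray:
    """All-Hessians reference: one exact Hessian per trajectory step."""
    n = trajectory.n_steps
    seq = np.empty((n, trajectory.n_dof, trajectory.n_dof))
    for k in range(n):
        seq[k] = surface.hessian(trajectory.positions[k])
    return seq


def hessians_to_cartesian(seq: np.ndarray, basis: NormalModeBasis) -> np.ndarray:
    """Transform a normal-mode Hessian sequence to Cartesian coordinates.

    H_cart = M^{1/2} L H_nm Lᵀ M^{1/2} with L the mode matrix.
    """
    L = basis.mode_matrix
    sqm = np.sqrt(basis.masses)
    T = sqm[:, None] * L
    return np.einsum("ab,kbc,dc->kad", T, np.asarray(seq), T)


def concatenate_trajectories(trajs: Sequence[TrajectoryRecord]) -> TrajectoryRecord:
    """Stack an ensemble into one record (time order within each member)."""
    if not trajs:
        raise ValueError("empty ensemble")
    g = None
    if all(t.gradients is not None for t in trajs):
        g = np.vstack([t.gradients for t in trajs])
    return TrajectoryRecord(
        dt=trajs[0].dt,
        positions=np.vstack([t.positions for t in trajs]),
        momenta=np.vstack([t.momenta for t in trajs]),
        energies=np.concatenate([t.energies for t in trajs]),
        gradients=g,
        coordinate_tag=trajs[0].coordinate_tag,
        masses=trajs[0].masses,
        meta={"ensemble_sizes": [t.n_steps for t in trajs]},
    )


def compare_methods(surface: PotentialSurface,
                    trajectory: Union[TrajectoryRecord, Sequence[TrajectoryRecord]],
                    budget: int,
                    seeds: Sequence[int] = (0, 1, 2),
                    training_space: str = "coords",
                    basis: Optional[NormalModeBasis] = None,
                    schedule_kwargs: Optional[dict] = None,
                    methods: Sequence[str] = ("ngas", "dbh", "bofill"),
                    ) -> dict:
    """Matched-budget comparison of the approximation methods.

    NGas uses ``n_neurons = budget`` (one run per seed); DBH bisects ρ to
    the budget within ±5%; the CFD chain refreshes every
    ceil(n_steps/budget) steps, applied per ensemble member when the input
    is a list of trajectories.  Returns a dict with per-method lists of
    :class:`ApproximationReport` and median σ_Hess values.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    ensemble = list(trajectory) if isinstance(trajectory, (list, tuple)) else None
    traj = concatenate_trajectories(ensemble) if ensemble else trajectory

    reference = exact_hessian_sequence(traj, surface)

    def finalize(seq):
        if basis is not None and traj.coordinate_tag == "normal_mode":
            return hessians_to_cartesian(seq, basis)
        return seq

    ref_c = finalize(reference)
    out = {"reports": {}, "median_sigma": {}, "budget_requested": budget}

    if "ngas" in methods:
        reports = []
        for seed in seeds:
            kwargs = dict(schedule_kwargs or {})
            kwargs["seed"] = seed
            sched = GasSchedule(**kwargs)
            seq, neurons, _ = ngas_run(traj, surface, n_neurons=budget,
                                       schedule=sched,
                                       training_space=training_space)
            rep = sigma_hess(ref_c, finalize(seq), method="ngas",
                             budget=neurons.budget,
                             metadata={"seed": seed,
                                       "training_space": training_space})
            reports.append(rep)
        out["reports"]["ngas"] = reports
        out["median_sigma"]["ngas"] = float(
            np.median([r.sigma_hess for r in reports]))

    if "dbh" in methods:
        rho, realized = rho_for_budget(traj, surface, budget)
        seq, db, b = dbh_run(traj, surface, rho)
        rep = sigma_hess(ref_c, finalize(seq), method="dbh", budget=b,
                         metadata={"rho": rho})
        out["reports"]["dbh"] = [rep]
        out["median_sigma"]["dbh"] = rep.sigma_hess

    for scheme in ("bofill", "sr1", "psb"):
        if scheme not in methods:
            continue
        if ensemble:
            seqs, b = [], 0
            for t in ensemble:
                refresh = -(-t.n_steps * len(ensemble) // budget)
                s, bi = cfd_run(t, surface, refresh_every=max(refresh, 1),
                                scheme=scheme)
                seqs.append(s)
                b += bi
            seq = np.concatenate(seqs, axis=0)
        else:
            refresh = -(-traj.n_steps // budget)
            seq, b = cfd_run(traj, surface, refresh_every=max(refresh, 1),
                             scheme=scheme)
        rep = sigma_hess(ref_c, finalize(seq), method=scheme, budget=b,
                         metadata={})
        out["reports"][scheme] = [rep]
        out["median_sigma"][scheme] = rep.sigma_hess

    return out
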