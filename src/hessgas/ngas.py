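"""Neural-gas landmark compression of molecular-dynamics trajectories.

The algorithm distributes ``n_neurons`` landmark geometries ("neurons")
over the cloud of trajectory configurations by annealed, rank-weighted
competitive learning (Martinetz–Schulten), refines each neuron to the
centroid of its Voronoi cell, and attaches one exactly computed Hessian
per neuron; every trajectory step then borrows the Hessian of its nearest
neuron.  The exact-Hessian budget is by construction the neuron count.

Training happens in a unit box: every component of the training vectors
(coordinates, optionally concatenated with potential gradients) is
affinely mapped to [0, 1] first, so all components carry equal weight in
the Euclidean clustering distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dynamics import TrajectoryRecord
from .surfaces import PotentialSurface, SurfaceEvaluationError

__all__ = [
    "ScalingMap",
    "GasSchedule",
    "NeuronSet",
    "VoronoiAssignment",
    "fit_scaling",
    "init_neurons",
    "rank_neurons",
    "anneal",
    "train_epoch",
    "centroid_refine",
    "attach_hessians",
    "approximate_trajectory_hessians",
    "build_extended_training_space",
    "train_ngas",
    "ngas_run",
    "voronoi_energy",
]


@dataclass
class ScalingMap:
    """Per-component affine map onto the closed unit box.

    Components with max == min are degenerate and map to the constant 0.5.
    """

    minima: np.ndarray
    maxima: np.ndarray

    def __post_init__(self):
        self.minima = np.asarray(self.minima, dtype=float)
        self.maxima = np.asarray(self.maxima, dtype=float)
        self._span = self.maxima - self.minima
        self._degenerate = self._span == 0.0
        self._safe_span = np.where(self._degenerate, 1.0, self._span)

    @property
    def d(self) -> int:
        return self.minima.size

    def forward(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        Q = (q - self.minima) / self._safe_span
        return np.where(self._degenerate, 0.5, Q)

    def inverse(self, Q: np.ndarray) -> np.ndarray:
        Q = np.asarray(Q, dtype=float)
        return np.where(self._degenerate, self.minima, self.minima + Q * self._safe_span)


def fit_scaling(training_points: np.ndarray) -> ScalingMap:
    """Column-wise min/max scaling of the training set onto the unit box."""
    pts = np.atleast_2d(np.asarray(training_points, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one training point")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite entries in training points")
    return ScalingMap(minima=pts.min(axis=0), maxima=pts.max(axis=0))


@dataclass
class GasSchedule:
    """Annealing schedule g(τ) = g_init (g_final/g_init)^{τ/τ_max}.

    Defaults follow the standard neural-gas recipe: the learning rate α
    decays 0.3 → 0.05 and the neighbourhood range λ decays 30 → 0.01 over
    ``n_epochs`` epochs, independent of the simulated system.
    """

    alpha_init: float = 0.3
    alpha_final: float = 0.05
    lambda_init: float = 30.0
    lambda_final: float = 0.01
    n_epochs: int = 40
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha_init", "alpha_final", "lambda_init", "lambda_final"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha_final > self.alpha_init:
            raise ValueError("alpha_final must not exceed alpha_init")
        if self.lambda_final > self.lambda_init:
            raise ValueError("lambda_final must not exceed lambda_init")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


def anneal(schedule: GasSchedule, which: str, epoch: int) -> float:
    """Geometric interpolation between the initial and final parameter value."""
    if which == "alpha":
        g0, g1 = schedule.alpha_init, schedule.alpha_final
    elif which == "lambda":
        g0, g1 = schedule.lambda_init, schedule.lambda_final
    else:
        raise ValueError("which must be 'alpha' or 'lambda'")
    if not 0 <= epoch <= schedule.n_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {schedule.n_epochs}]")
    return g0 * (g1 / g0) ** (epoch / schedule.n_epochs)


@dataclass
class NeuronSet:
    """Scaled-space neuron positions with their back-transform bookkeeping."""

    scaled_positions: np.ndarray                 # (n_neurons, d_train)
    scaling: ScalingMap
    training_space: str = "coords"               # or "coords_plus_gradients"
    n_dof: Optional[int] = None
    hessians: Optional[np.ndarray] = None        # (n_neurons, n_dof, n_dof)
    empty_cells: Optional[np.ndarray] = None
    budget: int = 0

    def __post_init__(self):
        self.scaled_positions = np.atleast_2d(
            np.asarray(self.scaled_positions, dtype=float))
        if self.training_space not in ("coords", "coords_plus_gradients"):
            raise ValueError(f"unknown training_space {self.training_space!r}")
        if self.n_dof is None:
            d = self.scaled_positions.shape[1]
            self.n_dof = d // 2 if self.training_space == "coords_plus_gradients" else d

    @property
    def n_neurons(self) -> int:
        return self.scaled_positions.shape[0]

    @property
    def d_train(self) -> int:
        return self.scaled_positions.shape[1]

    def geometries(self) -> np.ndarray:
        """Back-transformed neuron geometries in the original coordinates.

        Only the coordinate block is inverted in the gradient-extended space.
        """
        full = np.atleast_2d(self.scaling.inverse(self.scaled_positions))
        return full[:, : self.n_dof]


@dataclass
class VoronoiAssignment:
    """step index → nearest neuron index, plus per-neuron member lists."""

    labels: np.ndarray

    @property
    def n_points(self) -> int:
        return self.labels.size

    def members(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.labels == j)


def init_neurons(scaled_points: np.ndarray, n_neurons: int,
                 scaling: ScalingMap, training_space: str = "coords",
                 n_dof: Optional[int] = None) -> NeuronSet:
    """Initialize neurons on trajectory points at fixed step strides.

    Neuron j starts at scaled point floor(j·n/n_neurons); with 150 neurons
    over 3000 steps that is one landmark every 20 MD steps.
    """
    pts = np.atleast_2d(scaled_points)
    n = pts.shape[0]
    if not 1 <= n_neurons <= n:
        raise ValueError(
            f"n_neurons must be in [1, {n}] (requested {n_neurons})")
    idx = (np.arange(n_neurons) * n) // n_neurons
    return NeuronSet(scaled_positions=pts[idx].copy(), scaling=scaling,
                     training_space=training_space, n_dof=n_dof)


def rank_neurons(point: np.ndarray, neurons: NeuronSet) -> np.ndarray:
    """Distance ranks K_j: number of neurons strictly closer to the point.

    K is a permutation of {0, …, n_neurons−1}; ties go to the lower index.
    """
    diffs = neurons.scaled_positions - np.asarray(point)
    d2 = np.einsum("ij,ij->i", diffs, diffs)
    order = np.argsort(d2, kind="stable")
    K = np.empty(order.size, dtype=np.intp)
    K[order] = np.arange(order.size)
    return K


def train_epoch(neurons: NeuronSet, scaled_points: np.ndarray,
                schedule: GasSchedule, epoch: int,
                rng: np.random.Generator) -> NeuronSet:
    """One epoch of rank-weighted competitive updates.

    Visits every training point exactly once in a seeded random order;
    each visit moves every neuron by α(τ)·exp(−K_j/λ(τ))·(Q_i − Q̃_j),
    with the ranks K recomputed per visit.  Mutates and returns ``neurons``.
    """
    pts = np.atleast_2d(scaled_points)
    alpha = anneal(schedule, "alpha", epoch)
    lam = anneal(schedule, "lambda", epoch)
    W = neurons.scaled_positions
    # Rank-indexed weight lookup table for this epoch.
    wtab = alpha * np.exp(-np.arange(W.shape[0]) / lam)
    for i in rng.permutation(pts.shape[0]):
        point = pts[i]
        diffs = point - W
        d2 = np.einsum("ij,ij->i", diffs, diffs)
        order = np.argsort(d2, kind="stable")
        K = np.empty(order.size, dtype=np.intp)
        K[order] = np.arange(order.size)
        W += wtab[K][:, None] * diffs
    return neurons


def assign_voronoi(neurons: NeuronSet, scaled_points: np.ndarray) -> VoronoiAssignment:
    """Nearest-neuron label for every training point (ties → lower index)."""
    pts = np.atleast_2d(scaled_points)
    W = neurons.scaled_positions
    d2 = (
        np.einsum("ij,ij->i", pts, pts)[:, None]
        - 2.0 * pts @ W.T
        + np.einsum("ij,ij->i", W, W)[None, :]
    )
    return VoronoiAssignment(labels=np.argmin(d2, axis=1))


def voronoi_energy(neurons: NeuronSet, scaled_points: np.ndarray,
                   assignment: Optional[VoronoiAssignment] = None) -> float:
    """Discretized quantization error: mean squared member-to-neuron distance.

    The centroid is the exact minimizer of this functional cell by cell,
    which is what makes the single-pass refinement monotone.
    """
    pts = np.atleast_2d(scaled_points)
    if assignment is None:
        assignment = assign_voronoi(neurons, pts)
    diffs = pts - neurons.scaled_positions[assignment.labels]
    return float(np.mean(np.einsum("ij,ij->i", diffs, diffs)))


def centroid_refine(neurons: NeuronSet, scaled_points: np.ndarray,
                    iterate: bool = False, max_iter: int = 100):
    """Move each neuron to the centre of mass of its Voronoi cell.

    Single assign→move pass by default; ``iterate=True`` repeats until the
    assignment is stable (Lloyd iteration).  Neurons with empty cells are
    left in place and flagged in ``neurons.empty_cells``.

    Returns ``(neurons, assignment)`` with the assignment computed from the
    pre-move positions (single-pass mode) re-derived after the final move.
    """
    pts = np.atleast_2d(scaled_points)
    W = neurons.scaled_positions
    for _ in range(max_iter if iterate else 1):
        assignment = assign_voronoi(neurons, pts)
        moved = False
        empty = np.zeros(neurons.n_neurons, dtype=bool)
        for j in range(neurons.n_neurons):
            mem = assignment.members(j)
            if mem.size == 0:
                empty[j] = True
                continue
            target = pts[mem].mean(axis=0)
            if not np.array_equal(target, W[j]):
                W[j] = target
                moved = True
        if not (iterate and moved):
            break
    neurons.empty_cells = empty
    assignment = assign_voronoi(neurons, pts)
    return neurons, assignment


def attach_hessians(neurons: NeuronSet, surface: PotentialSurface,
                    scaled_points: Optional[np.ndarray] = None,
                    original_points: Optional[np.ndarray] = None) -> NeuronSet:
    """Evaluate one exact Hessian per neuron geometry.

    The exact-Hessian budget equals the neuron count.  If the surface
    fails at an off-trajectory neuron geometry, the neuron falls back to
    the Hessian at its nearest trajectory member's geometry (requires
    ``scaled_points``/``original_points``) and a warning is issued.
    """
    import warnings

    geoms = neurons.geometries()
    hessians = np.empty((neurons.n_neurons, neurons.n_dof, neurons.n_dof))
    for j, g in enumerate(geoms):
        try:
            H = surface.hessian(g)
        except SurfaceEvaluationError:
            if scaled_points is None or original_points is None:
                raise
            d2 = np.einsum("ij,ij->i",
                           scaled_points - neurons.scaled_positions[j],
                           scaled_points - neurons.scaled_positions[j])
            k = int(np.argmin(d2))
            warnings.warn(
                f"surface evaluation failed at neuron {j}; falling back to "
                f"the Hessian of trajectory member {k}")
            H = surface.hessian(original_points[k][: neurons.n_dof])
        hessians[j] = 0.5 * (H + H.T)
    neurons.hessians = hessians
    neurons.budget = neurons.n_neurons
    return neurons


def approximate_trajectory_hessians(neurons: NeuronSet,
                                    assignment: VoronoiAssignment) -> np.ndarray:
    """Per-step Hessian sequence: each step borrows its neuron's Hessian."""
    if neurons.hessians is None:
        raise RuntimeError("attach_hessians must run before approximation")
    labels = assignment.labels
    if np.any(labels < 0) or np.any(labels >= neurons.n_neurons):
        raise RuntimeError("assignment references a nonexistent neuron")
    return neurons.hessians[labels]


def build_extended_training_space(trajectory: TrajectoryRecord) -> np.ndarray:
    """Concatenate coordinates and potential gradients per step.

    Each of the 2·n_dof components is independently unit-box scaled later,
    so positions and forces enter the clustering distance with equal
    weight; Hessian evaluation uses only the coordinate block.
    """
    if trajectory.gradients is None:
        raise ValueError(
            "trajectory has no gradients; use training_space='coords'")
    return np.hstack([trajectory.positions, trajectory.gradients])


def train_ngas(points: np.ndarray, n_neurons: int,
               schedule: Optional[GasSchedule] = None,
               refine: bool = True):
    """Full neural-gas training on raw (unscaled) training vectors.

    Scales to the unit box, initializes at fixed strides, runs all epochs
    with a single seeded generator, and centroid-refines.  Returns
    ``(neurons, assignment, scaled_points)``.
    """
    schedule = schedule or GasSchedule()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    scaling = fit_scaling(pts)
    scaled = scaling.forward(pts)
    neurons = init_neurons(scaled, n_neurons, scaling)
    rng = np.random.default_rng(schedule.seed)
    for epoch in range(schedule.n_epochs):
        train_epoch(neurons, scaled, schedule, epoch, rng)
    if refine:
        neurons, assignment = centroid_refine(neurons, scaled)
    else:
        assignment = assign_voronoi(neurons, scaled)
    return neurons, assignment, scaled


def ngas_run(trajectory: TrajectoryRecord, surface: PotentialSurface,
             n_neurons: int, schedule: Optional[GasSchedule] = None,
             training_space: str = "coords"):
    """End-to-end neural-gas Hessian approximation for one trajectory.

    Returns ``(hessian_sequence, neurons, assignment)``; the exact-Hessian
    budget is ``neurons.budget == n_neurons``.
    """
    schedule = schedule or GasSchedule()
    if training_space == "coords_plus_gradients":
        raw = build_extended_training_space(trajectory)
    elif training_space == "coords":
        raw = trajectory.positions
    else:
        raise ValueError(f"unknown training_space {training_space!r}")
    scaling = fit_scaling(raw)
    scaled = scaling.forward(raw)
    neurons = init_neurons(scaled, n_neurons, scaling,
                           training_space=training_space,
                           n_dof=trajectory.n_dof)
    rng = np.random.default_rng(schedule.seed)
    for epoch in range(schedule.n_epochs):
        train_epoch(neurons, scaled, schedule, epoch, rng)
    neurons, assignment = centroid_refine(neurons, scaled)
    attach_hessians(neurons, surface, scaled_points=scaled,
                    original_points=raw)
    return approximate_trajectory_hessians(neurons, assignment), neurons, assignment
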