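"""On-disk formats: trajectory bundles, multi-frame XYZ, Hessian stores.

Everything is plain text.  A trajectory bundle is a directory of
whitespace-delimited matrices (one step per row, C-locale floats at 17
significant digits) plus a ``meta.json``; Hessian sequences and neuron
sets follow the same convention with an indexed manifest.  Multi-frame
XYZ (Å) is read and written through MDAnalysis with an explicit Å→bohr
conversion.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import List, Optional

import numpy as np

from .dynamics import TrajectoryRecord
from .ngas import NeuronSet, ScalingMap, VoronoiAssignment

ANGSTROM_TO_BOHR = 1.0 / 0.529177210903  # CODATA 2018 Bohr radius in Å

__all__ = [
    "write_trajectory_bundle", "read_trajectory_bundle",
    "write_hessian_sequence", "read_hessian_sequence",
    "write_neuron_set", "read_neuron_set",
    "write_xyz", "read_xyz",
    "ANGSTROM_TO_BOHR",
]

_FMT = "%.17e"


class TrajectoryFormatError(ValueError):
    """A bundle or XYZ file failed validation."""


def write_trajectory_bundle(path, trajectory: TrajectoryRecord,
                            extra_meta: Optional[dict] = None) -> Path:
    """Write ``positions.dat``/``momenta.dat``/``gradients.dat``/``energies.dat`` + ``meta.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "positions.dat", trajectory.positions, fmt=_FMT)
    np.savetxt(path / "momenta.dat", trajectory.momenta, fmt=_FMT)
    np.savetxt(path / "energies.dat", trajectory.energies, fmt=_FMT)
    if trajectory.gradients is not None:
        np.savetxt(path / "gradients.dat", trajectory.gradients, fmt=_FMT)
    meta = {
        "dt": trajectory.dt,
        "coordinate_tag": trajectory.coordinate_tag,
        "masses": None if trajectory.masses is None else trajectory.masses.tolist(),
        "n_steps": trajectory.n_steps,
        "n_dof": trajectory.n_dof,
    }
    meta.update(trajectory.meta)
    meta.update(extra_meta or {})
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def _load_matrix(path: Path, n_cols: Optional[int] = None) -> np.ndarray:
    if not path.exists():
        raise TrajectoryFormatError(f"missing file: {path}")
    try:
        arr = np.loadtxt(path, ndmin=2)
    except ValueError as err:
        raise TrajectoryFormatError(f"ragged or unparsable rows in {path}: {err}") from err
    if n_cols is not None and arr.shape[1] != n_cols:
        raise TrajectoryFormatError(
            f"{path}: expected {n_cols} columns, found {arr.shape[1]}")
    return arr


def read_trajectory_bundle(path) -> TrajectoryRecord:
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise TrajectoryFormatError(f"missing file: {meta_path}")
    meta = json.loads(meta_path.read_text())
    for key in ("dt", "coordinate_tag"):
        if key not in meta:
            raise TrajectoryFormatError(f"{meta_path}: unit metadata {key!r} absent")
    n_dof = meta.get("n_dof")
    pos = _load_matrix(path / "positions.dat", n_dof)
    mom = _load_matrix(path / "momenta.dat", pos.shape[1])
    eng = _load_matrix(path / "energies.dat").ravel()
    grad = None
    if (path / "gradients.dat").exists():
        grad = _load_matrix(path / "gradients.dat", pos.shape[1])
    masses = meta.get("masses")
    keep = {k: v for k, v in meta.items()
            if k not in ("dt", "coordinate_tag", "masses", "n_steps", "n_dof")}
    return TrajectoryRecord(
        dt=float(meta["dt"]), positions=pos, momenta=mom, energies=eng,
        gradients=grad, coordinate_tag=meta["coordinate_tag"],
        masses=None if masses is None else np.asarray(masses), meta=keep)


# ----------------------------------------------------------------------
# Hessian sequences
# ----------------------------------------------------------------------

def write_hessian_sequence(path, sequence: np.ndarray,
                           prefix: str = "h", sym_tol: float = 1e-8) -> Path:
    """One matrix file per step plus a ``manifest.json``.

    Rejects matrices whose asymmetry exceeds ``sym_tol``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    seq = np.asarray(sequence, dtype=float)
    names = []
    for k, H in enumerate(seq):
        asym = float(np.max(np.abs(H - H.T)))
        if asym > sym_tol:
            raise ValueError(f"matrix {k} asymmetric beyond {sym_tol} (|ΔH|={asym:.2e})")
        name = f"{prefix}_{k:05d}.dat"
        np.savetxt(path / name, H, fmt=_FMT)
        names.append(name)
    (path / "manifest.json").write_text(json.dumps(
        {"n": len(names), "files": names, "shape": list(seq.shape[1:])}, indent=1))
    return path


def read_hessian_sequence(path) -> np.ndarray:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise TrajectoryFormatError(f"missing file: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    files = manifest["files"]
    if len(files) != manifest["n"]:
        raise TrajectoryFormatError(
            f"{manifest_path}: manifest n={manifest['n']} but {len(files)} files listed")
    out = []
    for name in files:
        f = path / name
        if not f.exists():
            raise TrajectoryFormatError(f"manifest references missing file: {f}")
        out.append(np.loadtxt(f, ndmin=2))
    return np.stack(out) if out else np.empty((0, 0, 0))


# ----------------------------------------------------------------------
# Neuron sets
# ----------------------------------------------------------------------

def write_neuron_set(path, neurons: NeuronSet,
                     assignment: Optional[VoronoiAssignment] = None) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "neurons.dat", neurons.scaled_positions, fmt=_FMT)
    np.savetxt(path / "neuron_geometries.dat", neurons.geometries(), fmt=_FMT)
    (path / "scaling.json").write_text(json.dumps({
        "minima": neurons.scaling.minima.tolist(),
        "maxima": neurons.scaling.maxima.tolist(),
        "training_space": neurons.training_space,
        "n_dof": neurons.n_dof,
        "budget": neurons.budget,
    }, indent=1))
    if neurons.hessians is not None:
        write_hessian_sequence(path / "neuron_hessians", neurons.hessians)
    if assignment is not None:
        np.savetxt(path / "assignment.dat",
                   np.column_stack([np.arange(assignment.n_points),
                                    assignment.labels]), fmt="%d")
    return path


def read_neuron_set(path):
    """Returns ``(NeuronSet, VoronoiAssignment or None)``."""
    path = Path(path)
    scal = json.loads((path / "scaling.json").read_text())
    neurons = NeuronSet(
        scaled_positions=np.loadtxt(path / "neurons.dat", ndmin=2),
        scaling=ScalingMap(minima=np.asarray(scal["minima"]),
                           maxima=np.asarray(scal["maxima"])),
        training_space=scal["training_space"],
        n_dof=scal["n_dof"],
    )
    neurons.budget = scal.get("budget", 0)
    if (path / "neuron_hessians" / "manifest.json").exists():
        neurons.hessians = read_hessian_sequence(path / "neuron_hessians")
    assignment = None
    if (path / "assignment.dat").exists():
        lab = np.loadtxt(path / "assignment.dat", dtype=int, ndmin=2)
        assignment = VoronoiAssignment(labels=lab[:, 1])
    return neurons, assignment


# ----------------------------------------------------------------------
# Multi-frame XYZ (Cartesian, Å on disk)
# ----------------------------------------------------------------------

def write_xyz(path, positions_bohr: np.ndarray, elements: List[str],
              comment: str = "frame") -> Path:
    """Write an (n_frames, n_atoms*3) Cartesian trajectory as multi-frame XYZ in Å."""
    import MDAnalysis as mda

    path = Path(path)
    pos = np.asarray(positions_bohr, dtype=float)
    n_atoms = len(elements)
    if pos.shape[1] != 3 * n_atoms:
        raise ValueError(f"positions have {pos.shape[1]} columns for {n_atoms} atoms")
    u = mda.Universe.empty(n_atoms, trajectory=True)
    u.add_TopologyAttr("names", elements)
    u.add_TopologyAttr("elements", elements)
    with mda.Writer(str(path), n_atoms, remark=comment) as w:
        for frame in pos:
            u.atoms.positions = frame.reshape(n_atoms, 3) / ANGSTROM_TO_BOHR
            w.write(u.atoms)
    return path


def read_xyz(path):
    """Read a multi-frame XYZ; returns ``(positions_bohr, elements)``.

    Atom counts must agree across frames; coordinates are converted from
    Å to bohr with the documented constant.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise TrajectoryFormatError(f"missing file: {path}")
    # Pre-validate frame consistency: MDAnalysis assumes a constant atom count.
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, counts, frame_no = 0, [], 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise TrajectoryFormatError(
                f"{path}: expected atom count at line {i + 1}")
        frame_no += 1
        counts.append(n)
        if counts[0] != n:
            raise TrajectoryFormatError(
                f"{path}: frame {frame_no} has {n} atoms, expected {counts[0]}")
        i += 2 + n
    u = mda.Universe(str(path))
    elements = [str(n) for n in u.atoms.names]
    frames = np.stack([u.atoms.positions.reshape(-1).astype(float).copy() * ANGSTROM_TO_BOHR
                       for _ in u.trajectory])
    return frames, elements
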