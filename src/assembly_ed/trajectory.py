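"""Trajectory containers and the canonical multi-frame XYZ exchange format.

Units are nm and ps throughout.  The XYZ flavour written here carries a
comment line ``t= <time_ps> box= <bx> <by> <bz>`` per frame so that time and
box metadata survive a round trip; coordinates are written with 6 decimals
(round-trip error <= 1e-5 nm by construction).  Coordinates are stored
unwrapped -- no periodic imaging is applied, true displacements are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .topology import AssemblyTopology


class TrajectoryError(ValueError):
    """Raised for malformed trajectory files or inconsistent containers."""


@dataclass
class TrajectorySet:
    """Frames x atoms x 3 coordinates (nm) with per-frame times (ps) and box (nm)."""

    coordinates: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, float)
        self.times = np.asarray(self.times, float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError("coordinates must have shape (frames, atoms, 3)")
        if self.times.shape != (self.n_frames,):
            raise TrajectoryError("times length must equal number of frames")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("times must be strictly increasing")
        if not np.all(np.isfinite(self.coordinates)):
            raise TrajectoryError("coordinates contain non-finite values")
        if self.box is not None:
            self.box = np.asarray(self.box, float)
            if self.box.shape == (3,):
                self.box = np.tile(self.box, (self.n_frames, 1))
            if self.box.shape != (self.n_frames, 3):
                raise TrajectoryError("box must have shape (frames, 3) or (3,)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def dt(self) -> float:
        """Sampling interval (ps); requires a uniform time grid."""
        if self.n_frames < 2:
            raise TrajectoryError("need >= 2 frames to define a sampling interval")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise TrajectoryError("non-uniform time grid has no single sampling interval")
        return float(steps[0])


@dataclass
class SubunitTrajectory:
    """Per-heterodimer slice of a trajectory, in canonical atom order.

    Canonical order is: alpha-monomer atoms then beta-monomer atoms, each
    ascending by atom id.  ``ordering_signature`` identifies that order so
    subunits extracted with the same selection can be safely concatenated.
    """

    dimer_id: int
    coordinates: np.ndarray  # (frames, subunit_atoms, 3) nm
    atom_ids: np.ndarray  # global atom ids, canonical order
    selection: str
    times: np.ndarray
    ordering_signature: tuple = field(default_factory=tuple)
    superposed: bool = False

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


# -- multi-frame XYZ -------------------------------------------------------------------


def write_trajectory(traj: TrajectorySet, path: str | Path, names=None) -> None:
    """Write a :class:`TrajectorySet` as multi-frame XYZ (nm, 6 decimals)."""
    n = traj.n_atoms
    if names is None:
        names = [f"X{i}" for i in range(n)]
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(str(n))
        comment = f"t= {traj.times[f]:.6f}"
        if traj.box is not None:
            b = traj.box[f]
            comment += f" box= {b[0]:.6f} {b[1]:.6f} {b[2]:.6f}"
        lines.append(comment)
        frame = traj.coordinates[f]
        for i in range(n):
            x, y, z = frame[i]
            lines.append(f"{names[i]} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory(path: str | Path, topology: AssemblyTopology | None = None) -> TrajectorySet:
    """Read a multi-frame XYZ trajectory.

    If a topology is given, every frame's atom count must match it.  A
    truncated or malformed frame raises :class:`TrajectoryError` naming the
    frame index.
    """
    raw = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    times: list[float] = []
    boxes: list[np.ndarray] = []
    have_box = False
    pos = 0
    frame_idx = 0
    while pos < len(raw):
        if not raw[pos].strip():
            pos += 1
            continue
        try:
            n = int(raw[pos].strip())
        except ValueError as exc:
            raise TrajectoryError(f"frame {frame_idx}: bad atom-count line") from exc
        if topology is not None and n != topology.n_atoms:
            raise TrajectoryError(
                f"frame {frame_idx}: atom count {n} does not match topology ({topology.n_atoms})"
            )
        if pos + 1 + n >= len(raw) + 1 and pos + 1 + n > len(raw):
            raise TrajectoryError(f"frame {frame_idx}: truncated (expected {n} atoms)")
        comment = raw[pos + 1].split()
        t = frame_idx * 1.0
        box = None
        for key, nvals in (("t=", 1), ("box=", 3)):
            if key in comment:
                k = comment.index(key)
                vals = [float(v) for v in comment[k + 1 : k + 1 + nvals]]
                if key == "t=":
                    t = vals[0]
                else:
                    box = np.array(vals)
        body = raw[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise TrajectoryError(f"frame {frame_idx}: truncated (expected {n} atoms)")
        coords = np.empty((n, 3))
        for i, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise TrajectoryError(f"frame {frame_idx}: malformed atom line {i}")
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        times.append(t)
        if box is not None:
            have_box = True
            boxes.append(box)
        elif have_box:
            raise TrajectoryError(f"frame {frame_idx}: box metadata missing")
        pos += 2 + n
        frame_idx += 1
    if not frames:
        raise TrajectoryError("no frames found")
    return TrajectorySet(
        coordinates=np.stack(frames),
        times=np.array(times),
        box=np.stack(boxes) if have_box else None,
        provenance=str(path),
    )


# -- subunit extraction ----------------------------------------------------------------


def extract_subunit(
    traj: TrajectorySet,
    topology: AssemblyTopology,
    dimer_id: int,
    selection: str = "protein",
) -> SubunitTrajectory:
    """Slice one heterodimer's trajectory in canonical atom order.

    The selection is resolved on the topology and intersected with the dimer's
    atoms; coordinates are copied.  Raises if the selection is empty within
    the dimer.
    """
    if traj.n_atoms != topology.n_atoms:
        raise TrajectoryError("trajectory atom count does not match topology")
    selected = set(topology.select(selection).tolist())
    alpha, beta = topology.dimer_monomers(dimer_id)
    ordered: list[int] = []
    signature: list[tuple] = []
    for mono, label in ((alpha, "alpha"), (beta, "beta")):
        for atom in topology.monomer_atoms(mono):
            if int(atom) in selected:
                ordered.append(int(atom))
                row = topology.atoms.iloc[int(atom)]
                signature.append((label, str(row["name"]), bool(row["backbone"])))
    if not ordered:
        raise TrajectoryError(
            f"selection {selection!r} is empty within dimer {dimer_id}"
        )
    ids = np.array(ordered)
    return SubunitTrajectory(
        dimer_id=dimer_id,
        coordinates=traj.coordinates[:, ids, :].copy(),
        atom_ids=ids,
        selection=selection,
        times=traj.times.copy(),
        ordering_signature=tuple(signature),
    )


def insert_subunit(traj: TrajectorySet, subunit: SubunitTrajectory) -> None:
    """Write a subunit's coordinates back into the parent trajectory in place."""
    if subunit.n_frames != traj.n_frames:
        raise TrajectoryError("frame count mismatch on re-insertion")
    traj.coordinates[:, subunit.atom_ids, :] = subunit.coordinates
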