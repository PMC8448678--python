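"""Protofilament bending-angle statistics.

The bending angle between two heterodimers is the angle between the two
lines connecting the centers of mass of the monomers within each heterodimer
(alpha COM -> beta COM).  Angles are unsigned, in degrees, in [0, 180].
The inter-dimer variant (adjacent dimers along one protofilament) is the
default; the intra-dimer variant compares the axes of the two monomer halves
within a single dimer, each half's axis running between the COMs of its two
terminal atom groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import AssemblyTopology, TopologyError
from .trajectory import TrajectorySet

PAIR_CLASSES = ("plus_vs_central", "minus_vs_central", "intra_pf_generic")


class BendingError(ValueError):
    pass


@dataclass
class BendingSummary:
    """Per-class mean +- std (degrees) and 1-degree histograms."""

    stats: pd.DataFrame  # columns: pair_class, mean_deg, std_deg, count
    histograms: dict[str, np.ndarray]  # class -> counts over 180 one-degree bins
    bin_edges: np.ndarray  # 0..180

    def class_mean(self, pair_class: str) -> float:
        row = self.stats[self.stats["pair_class"] == pair_class]
        if row.empty:
            raise BendingError(f"no records for class {pair_class!r}")
        return float(row["mean_deg"].iloc[0])


def monomer_com(frame: np.ndarray, topology: AssemblyTopology, monomer_id: int, weights=None) -> np.ndarray:
    """Mass-weighted center of one monomer in a single frame (nm)."""
    ids = topology.monomer_atoms(monomer_id)
    w = topology.masses[ids] if weights is None else np.asarray(weights, float)
    total = w.sum()
    if total <= 0:
        raise BendingError(f"monomer {monomer_id}: zero total mass")
    return (w @ frame[ids]) / total


def dimer_axis(frame: np.ndarray, topology: AssemblyTopology, dimer_id: int) -> np.ndarray:
    """Unit vector from the alpha-monomer COM to the beta-monomer COM."""
    alpha, beta = topology.dimer_monomers(dimer_id)
    d = monomer_com(frame, topology, beta) - monomer_com(frame, topology, alpha)
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise BendingError(f"dimer {dimer_id}: coincident monomer centers")
    return d / norm


def bending_angle(axis_i: np.ndarray, axis_j: np.ndarray) -> float:
    """Angle between two unit axes in degrees, clamped into [0, 180]."""
    dot = float(np.clip(np.dot(axis_i, axis_j), -1.0, 1.0))
    return float(np.degrees(np.arccos(dot)))


def _pair_class(topology: AssemblyTopology, dimer_i: int, dimer_j: int) -> str:
    classes = {topology.position_class(dimer_i), topology.position_class(dimer_j)}
    if classes & {"plus_end", "plus_corner"}:
        return "plus_vs_central"
    if classes & {"minus_end", "minus_corner"}:
        return "minus_vs_central"
    return "intra_pf_generic"


def _com_matrix(topology: AssemblyTopology) -> tuple[np.ndarray, np.ndarray]:
    """Mass-normalised (n_monomers, n_atoms) COM weight matrix + monomer id order."""
    mono_ids = topology.monomers["id"].to_numpy()
    W = np.zeros((mono_ids.size, topology.n_atoms))
    masses = topology.masses
    for row, m in enumerate(mono_ids):
        ids = topology.monomer_atoms(int(m))
        w = masses[ids]
        if w.sum() <= 0:
            raise BendingError(f"monomer {m}: zero total mass")
        W[row, ids] = w / w.sum()
    return W, mono_ids


def _all_axes(traj: TrajectorySet, topology: AssemblyTopology):
    """Unit dimer axes for every frame: (n_frames, n_dimers, 3) + dimer id order."""
    W, mono_ids = _com_matrix(topology)
    coms = np.einsum("ma,fax->fmx", W, traj.coordinates)  # (F, n_mono, 3)
    mono_row = {int(m): i for i, m in enumerate(mono_ids)}
    dimer_ids = sorted(int(d) for d in topology.dimers["id"])
    axes = np.empty((traj.n_frames, len(dimer_ids), 3))
    for col, d in enumerate(dimer_ids):
        alpha, beta = topology.dimer_monomers(d)
        v = coms[:, mono_row[beta]] - coms[:, mono_row[alpha]]
        norm = np.linalg.norm(v, axis=1, keepdims=True)
        if np.any(norm < 1e-12):
            raise BendingError(f"dimer {d}: coincident monomer centers in some frame")
        axes[:, col] = v / norm
    return axes, dimer_ids


def _intra_axes(traj: TrajectorySet, topology: AssemblyTopology):
    """Per-monomer half axes (terminal-group COM to terminal-group COM), unit length."""
    dimer_ids = sorted(int(d) for d in topology.dimers["id"])
    masses = topology.masses
    out = {}
    for d in dimer_ids:
        pair = []
        for mono in topology.dimer_monomers(d):
            ids = topology.monomer_atoms(mono)
            half = ids.size // 2
            lo, hi = ids[:half], ids[half:]
            w_lo, w_hi = masses[lo] / masses[lo].sum(), masses[hi] / masses[hi].sum()
            v = np.einsum("a,fax->fx", w_hi, traj.coordinates[:, hi]) - np.einsum(
                "a,fax->fx", w_lo, traj.coordinates[:, lo]
            )
            norm = np.linalg.norm(v, axis=1, keepdims=True)
            if np.any(norm < 1e-12):
                raise BendingError(f"monomer {mono}: degenerate half axis")
            pair.append(v / norm)
        out[d] = pair
    return out


def bending_series(
    traj: TrajectorySet,
    topology: AssemblyTopology,
    variant: str = "inter_dimer",
    aggregate: str = "frames",
) -> tuple[pd.DataFrame, BendingSummary]:
    """Bending angles for every frame and dimer pair, with per-class summaries.

    ``variant="inter_dimer"``: one record per frame per pair of adjacent
    dimers on the same protofilament; pairs touching a plus-end (minus-end)
    dimer are classed ``plus_vs_central`` (``minus_vs_central``), the rest
    ``intra_pf_generic``.  ``variant="intra_dimer"``: angle between the alpha
    and beta half-axes within each dimer, classed by the dimer's own position.
    A protofilament with a single dimer simply contributes no inter-dimer
    pairs.  ``aggregate="pairs"`` replaces per-frame records by time-averaged
    per-pair angles.
    """
    records: dict[str, list] = {k: [] for k in ("time", "pf", "dimer_i", "dimer_j", "pair_class", "angle_deg")}
    times = traj.times

    if variant == "inter_dimer":
        axes, dimer_ids = _all_axes(traj, topology)
        col = {d: i for i, d in enumerate(dimer_ids)}
        pf_of = {int(r["id"]): int(r["pf"]) for _, r in topology.dimers.iterrows()}
        for pf in topology.protofilaments:
            chain = topology.pf_dimers(pf)
            for di, dj in zip(chain, chain[1:]):
                dots = np.clip(np.einsum("fx,fx->f", axes[:, col[di]], axes[:, col[dj]]), -1.0, 1.0)
                ang = np.degrees(np.arccos(dots))
                cls = _pair_class(topology, di, dj)
                records["time"].extend(times)
                records["pf"].extend([pf_of[di]] * traj.n_frames)
                records["dimer_i"].extend([di] * traj.n_frames)
                records["dimer_j"].extend([dj] * traj.n_frames)
                records["pair_class"].extend([cls] * traj.n_frames)
                records["angle_deg"].extend(ang)
    elif variant == "intra_dimer":
        half_axes = _intra_axes(traj, topology)
        pf_of = {int(r["id"]): int(r["pf"]) for _, r in topology.dimers.iterrows()}
        for d, (va, vb) in half_axes.items():
            dots = np.clip(np.einsum("fx,fx->f", va, vb), -1.0, 1.0)
            ang = np.degrees(np.arccos(dots))
            cls = _pair_class(topology, d, d)
            records["time"].extend(times)
            records["pf"].extend([pf_of[d]] * traj.n_frames)
            records["dimer_i"].extend([d] * traj.n_frames)
            records["dimer_j"].extend([d] * traj.n_frames)
            records["pair_class"].extend([cls] * traj.n_frames)
            records["angle_deg"].extend(ang)
    else:
        raise BendingError(f"unknown variant {variant!r}")

    df = pd.DataFrame(records)
    df["variant"] = variant
    if aggregate == "pairs" and not df.empty:
        df = (
            df.groupby(["pf", "dimer_i", "dimer_j", "pair_class", "variant"], as_index=False)
            .agg(angle_deg=("angle_deg", "mean"), time=("time", "max"))
        )
    elif aggregate != "frames" and aggregate != "pairs":
        raise BendingError(f"unknown aggregate {aggregate!r}")

    edges = np.arange(0.0, 181.0)
    stats_rows = []
    histograms = {}
    for cls, grp in df.groupby("pair_class"):
        ang = grp["angle_deg"].to_numpy()
        stats_rows.append(
            {"pair_class": cls, "mean_deg": ang.mean(), "std_deg": ang.std(), "count": ang.size}
        )
        histograms[cls], _ = np.histogram(np.clip(ang, 0.0, 180.0 - 1e-12), bins=edges)
    stats = pd.DataFrame(stats_rows, columns=["pair_class", "mean_deg", "std_deg", "count"])
    return df, BendingSummary(stats=stats, histograms=histograms, bin_edges=edges)
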