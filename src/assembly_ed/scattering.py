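"""Single-particle dynamics observables: van Hove self-correlation, the
self-intermediate scattering function, and axis-resolved mass density profiles.

The self part of the van Hove function,

    G_s(r, t) = (1/N) sum_j < delta(r - |r_j(t0 + t) - r_j(t0)|) >,

is estimated by histogramming displacement magnitudes over particles and time
origins and normalising so that the radial integral of G_s * 4 pi r^2 dr is
one.  Its spatial Fourier transform for a scalar wavenumber q is the
self-intermediate scattering function; for an isotropic system the angular
average is exact and reduces to a sinc kernel,

    F_s(q, t) = (1/N) sum_j < sin(q dr_j) / (q dr_j) >,

with F_s(q, 0) = 1.  Internal wavenumbers are nm^-1; use
:func:`q_from_inverse_angstrom` at the boundary (1.26 A^-1 -> 12.6 nm^-1).
Displacements must be unwrapped; global center-of-mass motion is retained
unless ``remove_com`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import AssemblyTopology
from .trajectory import TrajectorySet

AXES = {"x": 0, "y": 1, "z": 2}


class ScatteringError(ValueError):
    pass


@dataclass
class VanHoveCurve:
    """Self van Hove function at one lag time."""

    r: np.ndarray  # bin centers (nm)
    G: np.ndarray  # probability density over displacement magnitude shells
    t: float  # lag (ps)
    bin_width: float
    n_particles: int
    n_time_origins: int
    selection: str = ""

    def normalization_integral(self) -> float:
        """Radial integral sum G * 4 pi r^2 dr; equals 1 for a proper self part."""
        return float(np.sum(self.G * 4.0 * np.pi * self.r**2 * self.bin_width))


@dataclass
class ISFCurve:
    """Self-intermediate scattering function F_s(q, t)."""

    q: float  # nm^-1
    t: np.ndarray  # lags (ps)
    F: np.ndarray
    origin_stride: int
    n_particles: int
    selection: str = ""


@dataclass
class IsfComparison:
    """Per-lag ordering of two ISF curves (the faster system relaxes below the slower)."""

    t: np.ndarray
    sign: np.ndarray  # sign(a - b) per lag
    fraction_a_below: float  # over positive lags
    first_relaxed_lag: float | None  # first t where both curves < threshold
    threshold: float
    indistinguishable: bool


@dataclass
class DensityProfile:
    """Time-averaged mass density (amu/nm^3) along one box axis, per species."""

    axis: str
    centers: np.ndarray  # nm
    densities: dict[str, np.ndarray]
    bin_width: float
    cross_section: float  # nm^2
    total_mass: dict[str, float]

    def integrated_mass(self, species: str) -> float:
        return float(np.sum(self.densities[species]) * self.bin_width * self.cross_section)


# -- helpers ---------------------------------------------------------------------------


def q_from_inverse_angstrom(q_angstrom: float) -> float:
    """Convert a wavenumber quoted in A^-1 to internal nm^-1 units."""
    return 10.0 * float(q_angstrom)


def _lag_frames(traj: TrajectorySet, t: float) -> int:
    dt = traj.dt
    lag = int(round(t / dt))
    if abs(lag * dt - t) > 1e-6 * max(dt, 1.0):
        raise ScatteringError(f"lag {t} ps is not a multiple of the sampling interval {dt} ps")
    if lag < 0 or lag >= traj.n_frames:
        raise ScatteringError(f"lag {t} ps beyond trajectory length")
    return lag


def _origins(traj: TrajectorySet, lag: int, stride: int, max_origin_fraction: float) -> np.ndarray:
    last = min(traj.n_frames - lag, max(int(np.ceil(traj.n_frames * max_origin_fraction)), 1))
    return np.arange(0, last, stride)


def _selected_coords(traj: TrajectorySet, atom_indices, remove_com: bool) -> np.ndarray:
    coords = traj.coordinates if atom_indices is None else traj.coordinates[:, atom_indices, :]
    if coords.shape[1] == 0:
        raise ScatteringError("selection contains no atoms")
    if remove_com:
        coords = coords - coords.mean(axis=1, keepdims=True)
    return coords


# -- operations ------------------------------------------------------------------------


def van_hove_self(
    traj: TrajectorySet,
    t_list,
    r_bins=100,
    r_max: float | None = None,
    atom_indices=None,
    origin_stride: int = 1,
    max_origin_fraction: float = 0.5,
    remove_com: bool = False,
    selection: str = "",
) -> list[VanHoveCurve]:
    """Self van Hove function at each requested lag time.

    ``r_bins`` is a bin count (with ``r_max`` defaulting to 1.05x the largest
    observed displacement over all requested lags) or an explicit edge array.
    """
    coords = _selected_coords(traj, atom_indices, remove_com)
    n_particles = coords.shape[1]
    lags = [_lag_frames(traj, t) for t in t_list]
    all_disp = []
    for lag in lags:
        origins = _origins(traj, lag, origin_stride, max_origin_fraction)
        d = coords[origins + lag] - coords[origins]
        all_disp.append((np.linalg.norm(d, axis=2).ravel(), origins.size))
    if np.isscalar(r_bins):
        if r_max is None:
            r_max = 1.05 * max(float(d.max(initial=0.0)) for d, _ in all_disp)
            r_max = max(r_max, 1e-6)
        edges = np.linspace(0.0, r_max, int(r_bins) + 1)
    else:
        edges = np.asarray(r_bins, float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = float(edges[1] - edges[0])
    curves = []
    for (dist, n_origins), t in zip(all_disp, t_list):
        counts, _ = np.histogram(dist, bins=edges)
        shell = 4.0 * np.pi * centers**2 * width
        G = counts / (dist.size * shell)
        curves.append(
            VanHoveCurve(
                r=centers,
                G=G,
                t=float(t),
                bin_width=width,
                n_particles=n_particles,
                n_time_origins=n_origins,
                selection=selection,
            )
        )
    return curves


def isf_self(
    traj: TrajectorySet,
    q: float,
    t_grid=None,
    atom_indices=None,
    origin_stride: int = 1,
    max_origin_fraction: float = 0.5,
    remove_com: bool = False,
    selection: str = "",
) -> ISFCurve:
    """Self-intermediate scattering function via the isotropic sinc kernel.

    ``t_grid`` defaults to every multiple of the sampling interval up to half
    the trajectory; origins run over every ``origin_stride``-th frame within
    the first ``max_origin_fraction`` of the trajectory.
    """
    if q <= 0:
        raise ScatteringError("q must be positive")
    coords = _selected_coords(traj, atom_indices, remove_com)
    if t_grid is None:
        dt = traj.dt
        t_grid = np.arange(0, traj.n_frames // 2 + 1) * dt
    t_grid = np.asarray(t_grid, float)
    F = np.empty(t_grid.size)
    for i, t in enumerate(t_grid):
        lag = _lag_frames(traj, t)
        if lag == 0:
            F[i] = 1.0
            continue
        origins = _origins(traj, lag, origin_stride, max_origin_fraction)
        d = np.linalg.norm(coords[origins + lag] - coords[origins], axis=2)
        # np.sinc(x) = sin(pi x)/(pi x); the limit d -> 0 is handled exactly
        F[i] = float(np.mean(np.sinc(q * d / np.pi)))
    return ISFCurve(
        q=float(q),
        t=t_grid,
        F=F,
        origin_stride=origin_stride,
        n_particles=coords.shape[1],
        selection=selection,
    )


def isf_from_van_hove(curves: list[VanHoveCurve], q: float) -> np.ndarray:
    """Sinc-kernel quadrature of G_s over its r grid: an independent route to F_s."""
    out = np.empty(len(curves))
    for i, c in enumerate(curves):
        kernel = np.sinc(q * c.r / np.pi)
        out[i] = float(np.sum(c.G * kernel * 4.0 * np.pi * c.r**2 * c.bin_width))
    return out


def compare_isf(a: ISFCurve, b: ISFCurve, threshold: float = 0.02) -> IsfComparison:
    """Ordering report between two ISF curves on the same (q, t) grid.

    Reports the per-lag sign of (a - b), the fraction of positive lags where
    a lies below b (a faster-relaxing system sits below a slower one), and
    the first lag where both curves have fallen below ``threshold`` (the
    "completely relaxed" criterion).
    """
    if abs(a.q - b.q) > 1e-9 * max(a.q, 1.0) or a.t.shape != b.t.shape or not np.allclose(a.t, b.t):
        raise ScatteringError("ISF curves are on different (q, t) grids")
    diff = a.F - b.F
    indistinguishable = bool(np.max(np.abs(diff)) < 1e-12)
    positive = a.t > 0
    fraction = float(np.mean(diff[positive] < 0)) if positive.any() else 0.0
    relaxed = (a.F < threshold) & (b.F < threshold)
    first = float(a.t[np.argmax(relaxed)]) if relaxed.any() else None
    return IsfComparison(
        t=a.t.copy(),
        sign=np.sign(diff),
        fraction_a_below=fraction,
        first_relaxed_lag=first,
        threshold=threshold,
        indistinguishable=indistinguishable,
    )


def density_profile(
    traj: TrajectorySet,
    topology: AssemblyTopology,
    axis: str,
    species: list[str],
    n_bins: int = 100,
) -> DensityProfile:
    """Time-averaged mass density along one box axis, per species.

    Coordinates are wrapped into the box along the chosen axis before
    histogramming, so the integral of each profile over the box recovers the
    species' total mass exactly.
    """
    axis = axis.lower()
    if axis not in AXES:
        raise ScatteringError(f"unknown axis {axis!r}")
    if traj.box is None:
        raise ScatteringError("density profile requires box dimensions")
    if np.ptp(traj.box, axis=0).max() > 1e-9:
        raise ScatteringError("density profile requires a constant box")
    ax = AXES[axis]
    box = traj.box[0]
    L = float(box[ax])
    cross = float(np.prod(np.delete(box, ax)))
    edges = np.linspace(0.0, L, n_bins + 1)
    width = L / n_bins
    masses = topology.masses
    densities: dict[str, np.ndarray] = {}
    totals: dict[str, float] = {}
    for sp in species:
        ids = topology.select(f"species={sp}") if sp in ("ion_Mg", "ion_Cl", "water") or sp.startswith("ion") else topology.select(sp if sp in ("protein", "backbone", "calpha", "sidechain") else f"species={sp}")
        if ids.size == 0:
            raise ScatteringError(f"species/selection {sp!r} selects no atoms")
        x = np.mod(traj.coordinates[:, ids, ax], L)
        w = np.broadcast_to(masses[ids], x.shape)
        counts, _ = np.histogram(x.ravel(), bins=edges, weights=w.ravel())
        mean_mass = counts / traj.n_frames
        densities[sp] = mean_mass / (width * cross)
        totals[sp] = float(masses[ids].sum())
    return DensityProfile(
        axis=axis,
        centers=0.5 * (edges[:-1] + edges[1:]),
        densities=densities,
        bin_width=width,
        cross_section=cross,
        total_mass=totals,
    )
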