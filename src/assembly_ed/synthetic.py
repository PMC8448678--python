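"""Synthetic tubulin-assembly builder and planted-mode trajectory generator.

This module builds toy assemblies (protofilament sheets and cylindrical
microtubule fragments) and generates trajectories whose internal dynamics are
*known by construction*: per-heterodimer fluctuations are a sum of a few
orthonormal planted modes with prescribed variances, plus isotropic Gaussian
noise, plus optional imposed protofilament bends.  Every downstream analysis
(PCA, bending statistics, scattering functions) can therefore be validated by
parameter recovery instead of against undeposited MD data.

It is a geometry-plus-noise generator: there is no force field, no energy and
no thermostat.

Conventions
-----------
* Units: nm, ps, amu.
* Monomer labels alternate alpha/beta along each protofilament; the dimer
  axis points alpha -> beta toward the plus end (+z).
* Planted modes live in the heterodimer's local frame (the frame of the
  canonical subunit template); the generator rotates them into each dimer's
  lattice placement.  Their construction projects out the six rigid-body
  degrees of freedom of the template, because downstream superposition
  removes exactly that subspace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .topology import SOLVENT_GROUP, AssemblyTopology, TopologyError, write_pdb, write_topology
from .trajectory import TrajectorySet, write_trajectory
from .superpose import kabsch_fit

ION_MASSES = {"ion_Mg": 24.305, "ion_Cl": 35.453}


class GeneratorError(ValueError):
    """Raised for invalid lattice specs or planted-mode sets."""


# -- specs -----------------------------------------------------------------------------


@dataclass
class LatticeSpec:
    """Geometry of a toy tubulin lattice.

    ``n_layers`` counts *monomer* layers (two per dimer layer), so it must be
    even.  ``monomer_spacing`` is the axial monomer-to-monomer distance and
    also sets the lateral protofilament spacing.  For cylinders, ``radius``
    is the mid-wall radius and ``helical_rise_per_pf`` the per-protofilament
    axial offset of the seam helix.
    """

    n_protofilaments: int
    n_layers: int
    geometry: str = "sheet"  # "sheet" | "cylinder"
    radius: float = 10.0
    monomer_spacing: float = 4.0
    atoms_per_monomer: int = 20
    helical_rise_per_pf: float = 12.0 / 13.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_protofilaments < 1:
            raise GeneratorError("n_protofilaments must be >= 1")
        if self.n_layers < 2 or self.n_layers % 2:
            raise GeneratorError("n_layers must be even (monomer layers, two per dimer)")
        if self.atoms_per_monomer < 4:
            raise GeneratorError("atoms_per_monomer must be >= 4")
        if self.monomer_spacing <= 0:
            raise GeneratorError("monomer_spacing must be positive")
        if self.geometry not in ("sheet", "cylinder"):
            raise GeneratorError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "cylinder" and self.n_protofilaments > 1:
            chord = 2.0 * self.radius * np.sin(np.pi / self.n_protofilaments)
            if chord < 0.75 * self.monomer_spacing:
                raise GeneratorError(
                    f"cylinder radius {self.radius} nm too small: protofilament chord "
                    f"spacing {chord:.3f} nm would overlap monomers "
                    f"(need >= {0.75 * self.monomer_spacing:.3f} nm)"
                )


@dataclass
class PlantedMode:
    direction: np.ndarray  # (3M,) unit vector in subunit coordinates
    variance: float  # nm^2
    label: str = ""


@dataclass
class BendSegment:
    """Imposed protofilament curl.

    Dimers of ``pf_id`` whose dimer-layer index falls in the inclusive range
    ``dimer_layers`` are rotated cumulatively about the local bending axis
    through their intra-dimer interface: the c-th dimer of the range tilts by
    ``c * target_angle_deg``, so every adjacent inter-dimer pair touched by
    the range shows exactly ``target_angle_deg``.  ``ramp_frames`` ramps the
    angle linearly from zero over that many frames, then holds.
    """

    pf_id: int
    dimer_layers: tuple[int, int]
    target_angle_deg: float
    ramp_frames: int = 0


@dataclass
class PlantedModes:
    """Orthonormal planted modes + isotropic noise floor + optional bend plan."""

    modes: list[PlantedMode]
    isotropic_noise_variance: float = 0.0  # nm^2 per coordinate
    bend_plan: list[BendSegment] | None = None
    #: optional Ornstein-Uhlenbeck correlation time (ps) for mode amplitudes;
    #: None means amplitudes i.i.d. per frame (PCA is insensitive to frame
    #: order, time-correlation only matters for ISF-style observables)
    amplitude_correlation_time: float | None = None

    def validate(self) -> None:
        if self.isotropic_noise_variance < 0:
            raise GeneratorError("isotropic_noise_variance must be >= 0")
        if not self.modes:
            return
        V = np.stack([np.asarray(m.direction, float) for m in self.modes])
        G = V @ V.T
        if np.max(np.abs(np.diag(G) - 1.0)) > 1e-10:
            raise GeneratorError("planted mode directions must be unit vectors")
        off = G - np.diag(np.diag(G))
        if np.max(np.abs(off)) > 1e-10:
            raise GeneratorError("planted mode directions must be mutually orthogonal")
        var = [m.variance for m in self.modes]
        if any(v <= 0 for v in var):
            raise GeneratorError("planted variances must be positive")
        if any(a < b for a, b in zip(var, var[1:])):
            raise GeneratorError("planted variances must be listed descending")


@dataclass
class TracerSpec:
    """Brownian tracer ensemble (fixture for the scattering observables)."""

    n_particles: int
    diffusion_coefficient: float  # nm^2/ps
    dt: float  # ps
    n_frames: int
    box: tuple[float, float, float] = (10.0, 10.0, 10.0)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_particles, self.n_frames) < 1:
            raise GeneratorError("n_particles and n_frames must be >= 1")
        if self.diffusion_coefficient < 0 or self.dt <= 0:
            raise GeneratorError("need diffusion_coefficient >= 0 and dt > 0")
        if min(self.box) <= 0:
            raise GeneratorError("box lengths must be positive")
        # rms displacement over the run must stay well inside half the box
        rms = np.sqrt(2.0 * self.diffusion_coefficient * self.dt * max(self.n_frames - 1, 1))
        if rms > min(self.box) / 4.0:
            raise GeneratorError(
                f"box too small: per-axis rms displacement {rms:.2f} nm over the run "
                f"exceeds min(box)/4 = {min(self.box) / 4.0:.2f} nm"
            )


# -- lattice construction --------------------------------------------------------------


def monomer_template(n_atoms: int, spacing: float) -> np.ndarray:
    """Deterministic atom pattern for one monomer: a conical helix.

    Chiral and non-collinear (so superposition and centers of mass are
    non-degenerate), extends 0.8*spacing axially and ~0.35*spacing laterally.
    """
    k = np.arange(n_atoms)
    t = k / max(n_atoms - 1, 1)
    ang = 2.399963 * k  # golden angle, avoids accidental symmetry
    r = 0.35 * spacing * (0.4 + 0.6 * t)
    return np.stack(
        [r * np.cos(ang), r * np.sin(ang), 0.8 * spacing * (t - 0.5)], axis=1
    )


def build_lattice(spec: LatticeSpec) -> tuple[AssemblyTopology, np.ndarray]:
    """Build a straight sheet or cylinder lattice of heterodimers.

    Returns the topology and the reference coordinates (n_atoms, 3) in nm.
    Dimers are initially straight; atom masses default to 1.  Position
    classes: minus_end / plus_end for the outermost dimer layers, central
    otherwise; on cylinders the seam protofilament's end dimers are the
    minus_corner / plus_corner (the outmost corner heterodimers).
    """
    spec.validate()
    n_dimer_layers = spec.n_layers // 2
    template = monomer_template(spec.atoms_per_monomer, spec.monomer_spacing)

    atoms: list[dict] = []
    monomers: list[dict] = []
    dimers: list[dict] = []
    coords: list[np.ndarray] = []
    n_backbone = int(np.ceil(spec.atoms_per_monomer / 2))

    for p in range(spec.n_protofilaments):
        for dl in range(n_dimer_layers):
            dimer_id = p * n_dimer_layers + dl
            if dl == 0:
                cls = "minus_corner" if (spec.geometry == "cylinder" and p == 0) else "minus_end"
            elif dl == n_dimer_layers - 1:
                cls = "plus_corner" if (spec.geometry == "cylinder" and p == 0) else "plus_end"
            else:
                cls = "central"
            dimers.append({"id": dimer_id, "pf": p, "layer": dl, "position_class": cls})
            for half, label in ((0, "alpha"), (1, "beta")):
                l = 2 * dl + half  # monomer layer
                monomer_id = p * spec.n_layers + l
                monomers.append({"id": monomer_id, "dimer": dimer_id, "label": label})
                z = l * spec.monomer_spacing
                if spec.geometry == "sheet":
                    center = np.array([p * spec.monomer_spacing, 0.0, z])
                    local = template
                else:
                    theta = 2.0 * np.pi * p / spec.n_protofilaments
                    center = np.array(
                        [
                            spec.radius * np.cos(theta),
                            spec.radius * np.sin(theta),
                            z + p * spec.helical_rise_per_pf,
                        ]
                    )
                    # local +x points radially outward
                    local = template @ Rotation.from_euler("z", theta).as_matrix().T
                coords.append(local + center)
                for a in range(spec.atoms_per_monomer):
                    atoms.append(
                        {
                            "id": len(atoms),
                            "name": f"X{a:03d}",
                            "mass": 1.0,
                            "species": "protein",
                            "backbone": a < n_backbone,
                            "calpha": a < n_backbone and a % 2 == 0,
                            "monomer": monomer_id,
                        }
                    )

    topology = AssemblyTopology(
        atoms=pd.DataFrame(atoms),
        monomers=pd.DataFrame(monomers),
        dimers=pd.DataFrame(dimers),
    )
    return topology, np.concatenate(coords, axis=0)


def default_box(reference: np.ndarray, padding: float = 2.0) -> np.ndarray:
    """Axis-aligned bounding box of the reference plus padding on both sides."""
    extent = reference.max(axis=0) - reference.min(axis=0)
    return extent + 2.0 * padding


def add_ions(
    topology: AssemblyTopology,
    reference: np.ndarray,
    counts: dict[str, int],
    box: np.ndarray,
    seed: int = 0,
) -> tuple[AssemblyTopology, np.ndarray]:
    """Append ions uniformly distributed in the box, as the reserved solvent group.

    ``counts`` maps ion species (``ion_Mg``, ``ion_Cl``) to counts; ions get
    their atomic masses.  Returns a new (topology, reference) pair.
    """
    rng = np.random.default_rng(seed)
    atoms = topology.atoms.to_dict(orient="records")
    new_coords = [np.asarray(reference, float)]
    box = np.asarray(box, float)
    lo = reference.min(axis=0) - (box - (reference.max(axis=0) - reference.min(axis=0))) / 2
    for species in sorted(counts):
        n = counts[species]
        if species not in ION_MASSES:
            raise TopologyError(f"unsupported ion species {species!r}")
        pos = lo + rng.random((n, 3)) * box
        new_coords.append(pos)
        tag = species.split("_")[1].upper()
        for i in range(n):
            atoms.append(
                {
                    "id": len(atoms),
                    "name": f"{tag}{i}",
                    "mass": ION_MASSES[species],
                    "species": species,
                    "backbone": False,
                    "calpha": False,
                    "monomer": SOLVENT_GROUP,
                }
            )
    out = AssemblyTopology(
        atoms=pd.DataFrame(atoms),
        monomers=topology.monomers.copy(),
        dimers=topology.dimers.copy(),
    )
    return out, np.concatenate(new_coords, axis=0)


# -- planted-mode construction ---------------------------------------------------------


def subunit_reference(topology: AssemblyTopology, reference: np.ndarray, dimer_id: int = 0) -> np.ndarray:
    """Canonical subunit template: one dimer's reference coordinates, centered."""
    ids = topology.dimer_atoms(dimer_id)
    coords = reference[ids]
    return coords - coords.mean(axis=0)


def rigid_basis(reference: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3A) of rigid-body displacements of a structure."""
    ref = np.asarray(reference, float)
    A = ref.shape[0]
    c = ref.mean(axis=0)
    basis = []
    for ax in range(3):
        v = np.zeros((A, 3))
        v[:, ax] = 1.0
        basis.append(v.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(e, ref - c).ravel())
    Q, _ = np.linalg.qr(np.stack(basis).T)
    return Q.T


def _hinge_patterns(ref: np.ndarray) -> dict[str, np.ndarray]:
    """Raw internal-motion patterns on a two-monomer template (pre-orthogonalisation)."""
    A = ref.shape[0]
    half = A // 2
    sign = np.where(np.arange(A) < half, -1.0, 1.0)[:, None]
    interface = ref.mean(axis=0)
    com_alpha = ref[:half].mean(axis=0)
    com_beta = ref[half:].mean(axis=0)
    x, z = np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])
    # wobble: the two monomers hinge in opposite senses about the lateral axis
    wobble = sign * np.cross(x, ref - interface)
    # twist: counter-rotation of the monomers about the common (dimer) axis
    centers = np.where(np.arange(A)[:, None] < half, com_alpha, com_beta)
    twist = sign * np.cross(z, ref - centers)
    # compression: axial contraction toward the inter-monomer interface
    compress = -np.outer(ref[:, 2] - interface[2], z)
    return {"wobble": wobble.ravel(), "twist": twist.ravel(), "compress": compress.ravel()}


def make_planted_modes(
    reference_subunit: np.ndarray,
    variance_fractions=(0.15, 0.10, 0.08),
    total_variance: float = 0.03,
    seed: int = 0,
    bend_plan: list[BendSegment] | None = None,
    amplitude_correlation_time: float | None = None,
) -> PlantedModes:
    """Build orthonormal planted modes carrying given fractions of a total variance.

    The first three modes are wobbling / rotation / compression analogues of
    tubulin's dominant heterodimer motions; further modes (if more fractions
    are requested) are random internal directions.  All directions have the
    template's rigid-body subspace projected out before orthonormalisation,
    and the isotropic noise level is set so that the noise carries the
    remaining ``1 - sum(fractions)`` of the total variance spread over all
    3A coordinates.
    """
    ref = np.asarray(reference_subunit, float)
    dim = ref.size
    fr = np.asarray(variance_fractions, float)
    if np.any(fr <= 0) or fr.sum() >= 1.0:
        raise GeneratorError("variance fractions must be positive with sum < 1")
    if np.any(np.diff(fr) > 0):
        raise GeneratorError("variance fractions must be non-increasing")
    rigid = rigid_basis(ref)
    rng = np.random.default_rng(seed)
    raw = _hinge_patterns(ref)
    labels = list(raw)[: len(fr)]
    vectors = [raw[l] for l in labels]
    while len(vectors) < len(fr):
        vectors.append(rng.standard_normal(dim))
        labels.append(f"random{len(vectors)}")
    ortho: list[np.ndarray] = []
    for v in vectors:
        v = v - rigid.T @ (rigid @ v)
        for u in ortho:
            v = v - u * (u @ v)
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise GeneratorError("degenerate planted-mode pattern")
        ortho.append(v / norm)
    noise_var = (1.0 - fr.sum()) * total_variance / dim
    modes = [
        PlantedMode(direction=u, variance=float(f * total_variance), label=l)
        for u, f, l in zip(ortho, fr, labels)
    ]
    planted = PlantedModes(
        modes=modes,
        isotropic_noise_variance=noise_var,
        bend_plan=bend_plan,
        amplitude_correlation_time=amplitude_correlation_time,
    )
    planted.validate()
    return planted


# -- trajectory generation -------------------------------------------------------------


def _mode_amplitudes(rng, n_frames: int, variance: float, tau: float | None, dt: float) -> np.ndarray:
    """i.i.d. Gaussian amplitudes, or a stationary Ornstein-Uhlenbeck path if tau is set."""
    sigma = np.sqrt(variance)
    if tau is None:
        return rng.normal(0.0, sigma, size=n_frames)
    rho = np.exp(-dt / tau)
    a = np.empty(n_frames)
    a[0] = rng.normal(0.0, sigma)
    innov = rng.normal(0.0, sigma * np.sqrt(1.0 - rho * rho), size=n_frames - 1)
    for i in range(1, n_frames):
        a[i] = rho * a[i - 1] + innov[i - 1]
    return a


def generate_trajectory(
    topology: AssemblyTopology,
    reference: np.ndarray,
    planted: PlantedModes,
    n_frames: int,
    seed: int,
    dt: float = 10.0,
    box: np.ndarray | None = None,
    solvent_diffusion: float = 0.0,
) -> TrajectorySet:
    """Generate an assembly trajectory with the planted dynamics.

    Per dimer and frame, subunit coordinates are
    ``template + sum_k a_k * mode_k + noise`` in the dimer's local frame,
    with amplitudes ``a_k ~ N(0, variance_k)`` drawn independently per dimer,
    then placed into the lattice and optionally curled by the bend plan.
    Solvent atoms (ions) perform an independent Gaussian random walk with
    diffusion coefficient ``solvent_diffusion``.  Identical seeds give
    bit-identical trajectories.
    """
    planted.validate()
    reference = np.asarray(reference, float)
    template = subunit_reference(topology, reference)
    dim = template.size
    for m in planted.modes:
        if np.asarray(m.direction).shape != (dim,):
            raise GeneratorError(
                f"mode dimensionality {np.asarray(m.direction).size} != 3 x atoms per dimer ({dim})"
            )
    rng = np.random.default_rng(seed)
    n_atoms = topology.n_atoms
    coords = np.broadcast_to(reference, (n_frames, n_atoms, 3)).copy()

    mode_matrix = (
        np.stack([m.direction for m in planted.modes]) if planted.modes else np.zeros((0, dim))
    )
    variances = np.array([m.variance for m in planted.modes])
    tau = planted.amplitude_correlation_time
    sigma_noise = np.sqrt(planted.isotropic_noise_variance)

    # per-dimer placement: exact rigid transform template -> lattice site
    dimer_ids = sorted(int(d) for d in topology.dimers["id"])
    placements = {}
    for d in dimer_ids:
        ids = topology.dimer_atoms(d)
        tf, fitted = kabsch_fit(template, reference[ids])
        placements[d] = (ids, tf)

    A_d = template.shape[0]
    for d in dimer_ids:
        ids, tf = placements[d]
        amps = np.stack(
            [_mode_amplitudes(rng, n_frames, v, tau, dt) for v in variances], axis=1
        ) if len(variances) else np.zeros((n_frames, 0))
        disp = (amps @ mode_matrix).reshape(n_frames, A_d, 3)
        if sigma_noise > 0:
            disp = disp + rng.normal(0.0, sigma_noise, size=(n_frames, A_d, 3))
        local = template[None, :, :] + disp
        coords[:, ids, :] = local @ tf.rotation.T + tf.translation

    if planted.bend_plan:
        _apply_bend_plan(topology, reference, coords, planted.bend_plan, placements)

    solvent_ids = topology.atoms.loc[topology.atoms["monomer"] == SOLVENT_GROUP, "id"].to_numpy()
    if solvent_ids.size:
        start = reference[solvent_ids]
        steps = rng.normal(
            0.0,
            np.sqrt(max(2.0 * solvent_diffusion * dt, 0.0)),
            size=(n_frames - 1, solvent_ids.size, 3),
        ) if n_frames > 1 and solvent_diffusion > 0 else np.zeros((max(n_frames - 1, 0), solvent_ids.size, 3))
        walk = np.concatenate([np.zeros((1, solvent_ids.size, 3)), np.cumsum(steps, axis=0)])
        coords[:, solvent_ids, :] = start[None] + walk

    if box is None:
        box = default_box(reference)
    times = np.arange(n_frames) * dt
    return TrajectorySet(
        coordinates=coords, times=times, box=np.asarray(box, float), provenance=f"synthetic seed={seed}"
    )


def _apply_bend_plan(topology, reference, coords, bend_plan, placements) -> None:
    """Curl protofilament segments in place (cumulative rigid dimer rotations)."""
    n_frames = coords.shape[0]
    for seg in bend_plan:
        dimers = [
            d
            for d in topology.pf_dimers(seg.pf_id)
            if seg.dimer_layers[0] <= int(topology.dimers.set_index("id").loc[d, "layer"]) <= seg.dimer_layers[1]
        ]
        if not dimers:
            raise GeneratorError(f"bend segment matches no dimers on pf {seg.pf_id}")
        if seg.ramp_frames > 0:
            ramp = np.minimum(np.arange(n_frames) / seg.ramp_frames, 1.0)
        else:
            ramp = np.ones(n_frames)
        for c, d in enumerate(dimers, start=1):
            ids, tf = placements[d]
            axis = tf.rotation @ np.array([1.0, 0.0, 0.0])  # local lateral axis
            alpha, beta = topology.dimer_monomers(d)
            pivot = 0.5 * (
                reference[topology.monomer_atoms(alpha)].mean(axis=0)
                + reference[topology.monomer_atoms(beta)].mean(axis=0)
            )
            angles = np.deg2rad(seg.target_angle_deg * c * ramp)
            R = Rotation.from_rotvec(np.outer(angles, axis)).as_matrix()  # (F, 3, 3)
            block = coords[:, ids, :] - pivot
            coords[:, ids, :] = np.einsum("fax,fyx->fay", block, R) + pivot


# -- Brownian tracers ------------------------------------------------------------------


def generate_tracers(spec: TracerSpec) -> TrajectorySet:
    """Independent Gaussian random walks: per-axis step variance 2*D*dt.

    Coordinates are stored unwrapped (true displacements retained); starting
    positions are uniform in the box.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, float)
    start = rng.random((spec.n_particles, 3)) * box
    scale = np.sqrt(2.0 * spec.diffusion_coefficient * spec.dt)
    if spec.n_frames > 1 and scale > 0:
        steps = rng.normal(0.0, scale, size=(spec.n_frames - 1, spec.n_particles, 3))
        walk = np.concatenate([np.zeros((1, spec.n_particles, 3)), np.cumsum(steps, axis=0)])
    else:
        walk = np.zeros((spec.n_frames, spec.n_particles, 3))
    return TrajectorySet(
        coordinates=start[None] + walk,
        times=np.arange(spec.n_frames) * spec.dt,
        box=box,
        provenance=f"tracers seed={spec.seed}",
    )


def tracer_topology(n_particles: int, species: str = "protein", mass: float = 1.0) -> AssemblyTopology:
    """Minimal point-particle topology for tracer ensembles (no hierarchy)."""
    atoms = pd.DataFrame(
        {
            "id": np.arange(n_particles),
            "name": [f"T{i}" for i in range(n_particles)],
            "mass": mass,
            "species": species,
            "backbone": False,
            "calpha": False,
            "monomer": SOLVENT_GROUP,
        }
    )
    empty_m = pd.DataFrame({"id": [], "dimer": [], "label": []})
    empty_d = pd.DataFrame({"id": [], "pf": [], "layer": [], "position_class": []})
    return AssemblyTopology(atoms=atoms, monomers=empty_m, dimers=empty_d)


# -- export ----------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(path: str | Path, **sections) -> None:
    """Record specs and seeds as JSON so any output can be regenerated."""
    payload = {}
    for key, value in sections.items():
        if hasattr(value, "__dataclass_fields__"):
            value = asdict(value)
        payload[key] = _jsonable(value)
    Path(path).write_text(json.dumps(payload, indent=1))


def export_system(
    outdir: str | Path,
    topology: AssemblyTopology,
    reference: np.ndarray,
    trajectory: TrajectorySet | None = None,
    **manifest_sections,
) -> None:
    """Emit topology (JSON map + PDB), coordinates (XYZ) and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_topology(topology, outdir / "topology.json")
    write_pdb(topology, reference, outdir / "topology.pdb")
    names = topology.atoms["name"].tolist()
    ref_traj = TrajectorySet(coordinates=reference[None], times=np.zeros(1))
    write_trajectory(ref_traj, outdir / "reference.xyz", names=names)
    if trajectory is not None:
        write_trajectory(trajectory, outdir / "trajectory.xyz", names=names)
    if manifest_sections:
        write_manifest(outdir / "manifest.json", **manifest_sections)
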