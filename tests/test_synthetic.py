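import numpy as np
import pytest

from assembly_ed import (
    BendSegment,
    LatticeSpec,
    PlantedMode,
    PlantedModes,
    TracerSpec,
    build_lattice,
    generate_tracers,
    generate_trajectory,
    make_planted_modes,
    subunit_reference,
)
from assembly_ed.synthetic import GeneratorError, rigid_basis


def test_zero_variance_zero_noise_reproduces_reference(small_sheet):
    _, topology, reference = small_sheet
    planted = PlantedModes(modes=[], isotropic_noise_variance=0.0)
    traj = generate_trajectory(topology, reference, planted, n_frames=4, seed=0)
    assert np.allclose(traj.coordinates, reference[None], atol=1e-12)


def test_same_seed_bit_identical(small_sheet):
    _, topology, reference = small_sheet
    template = subunit_reference(topology, reference)
    planted = make_planted_modes(template, (0.15, 0.10, 0.08), 0.03, seed=0)
    a = generate_trajectory(topology, reference, planted, 20, seed=42)
    b = generate_trajectory(topology, reference, planted, 20, seed=42)
    assert np.array_equal(a.coordinates, b.coordinates)
    c = generate_trajectory(topology, reference, planted, 20, seed=43)
    assert not np.array_equal(a.coordinates, c.coordinates)


def test_planted_modes_are_internal_and_orthonormal(small_sheet):
    _, topology, reference = small_sheet
    template = subunit_reference(topology, reference)
    planted = make_planted_modes(template, (0.15, 0.10, 0.08, 0.05), 0.03, seed=1)
    V = np.stack([m.direction for m in planted.modes])
    assert np.allclose(V @ V.T, np.eye(4), atol=1e-10)
    # no rigid-body leakage: superposition must not eat planted variance
    rigid = rigid_basis(template)
    assert np.max(np.abs(rigid @ V.T)) < 1e-10


def test_sample_variance_matches_planted_direct_projection(small_sheet):
    """Independent check: project raw lab-frame displacements of a single-dimer
    lattice onto the planted directions and compare sample variances."""
    spec = LatticeSpec(1, 2, "sheet", atoms_per_monomer=8)
    topology, reference = build_lattice(spec)
    template = subunit_reference(topology, reference)
    planted = make_planted_modes(template, (0.15, 0.10, 0.08), 0.03, seed=5)
    n = 6000
    traj = generate_trajectory(topology, reference, planted, n, seed=5)
    disp = (traj.coordinates - reference[None]).reshape(n, -1)
    for mode in planted.modes:
        amps = disp @ mode.direction
        sample = amps.var()
        # noise adds its per-coordinate variance on top of the planted one
        expect = mode.variance + planted.isotropic_noise_variance
        se = expect * np.sqrt(2.0 / n)
        assert abs(sample - expect) < 3 * se


def test_non_orthonormal_modes_rejected(small_sheet):
    _, topology, reference = small_sheet
    template = subunit_reference(topology, reference)
    dim = template.size
    v = np.zeros(dim)
    v[0] = 1.0
    w = np.zeros(dim)
    w[0] = 0.8
    w[1] = 0.6
    bad = PlantedModes(modes=[PlantedMode(v, 0.1), PlantedMode(w, 0.05)])
    with pytest.raises(GeneratorError, match="orthogonal"):
        generate_trajectory(topology, reference, bad, 3, seed=0)


def test_mode_dimension_mismatch_rejected(small_sheet):
    _, topology, reference = small_sheet
    v = np.zeros(12)
    v[0] = 1.0
    bad = PlantedModes(modes=[PlantedMode(v, 0.1)])
    with pytest.raises(GeneratorError, match="dimensionality"):
        generate_trajectory(topology, reference, bad, 3, seed=0)


def test_ou_amplitudes_are_time_correlated(small_sheet):
    _, topology, reference = small_sheet
    template = subunit_reference(topology, reference)
    spec = LatticeSpec(1, 2, "sheet", atoms_per_monomer=8)
    topo1, ref1 = build_lattice(spec)
    tmpl1 = subunit_reference(topo1, ref1)
    planted = make_planted_modes(tmpl1, (0.3,), 0.05, seed=2,
                                 amplitude_correlation_time=100.0)
    traj = generate_trajectory(topo1, ref1, planted, 3000, seed=2, dt=10.0)
    amps = (traj.coordinates - ref1[None]).reshape(3000, -1) @ planted.modes[0].direction
    lag1 = np.corrcoef(amps[:-1], amps[1:])[0, 1]
    assert lag1 > 0.7  # exp(-10/100) ~ 0.905 up to noise dilution


def test_bend_recovery_noise_free(small_sheet):
    from assembly_ed import bending_series

    _, topology, reference = small_sheet
    plan = [BendSegment(pf_id=1, dimer_layers=(2, 2), target_angle_deg=11.0)]
    planted = PlantedModes(modes=[], bend_plan=plan)
    traj = generate_trajectory(topology, reference, planted, 3, seed=0)
    records, _ = bending_series(traj, topology)
    bent = records[(records["pf"] == 1) & (records["dimer_j"] == 5)]
    assert np.allclose(bent["angle_deg"], 11.0, atol=0.5)
    untouched = records[records["pf"] != 1]
    assert np.max(untouched["angle_deg"]) < 1e-6


def test_tracers_static_when_d_zero():
    spec = TracerSpec(n_particles=50, diffusion_coefficient=0.0, dt=1.0, n_frames=10)
    traj = generate_tracers(spec)
    assert np.allclose(traj.coordinates, traj.coordinates[:1])


def test_tracer_msd_matches_closed_form():
    """MSD(t) = 6 D t for free diffusion, within 5% at n = 1e4."""
    D, dt = 1e-3, 1.0
    spec = TracerSpec(n_particles=10_000, diffusion_coefficient=D, dt=dt,
                      n_frames=40, seed=9)
    traj = generate_tracers(spec)
    for lag in (5, 10, 20):
        disp = traj.coordinates[lag] - traj.coordinates[0]
        msd = np.mean(np.sum(disp**2, axis=1))
        assert msd == pytest.approx(6 * D * lag * dt, rel=0.05)


def test_tracer_determinism_and_box_guard():
    spec = TracerSpec(n_particles=20, diffusion_coefficient=1e-3, dt=1.0, n_frames=8, seed=4)
    a, b = generate_tracers(spec), generate_tracers(spec)
    assert np.array_equal(a.coordinates, b.coordinates)
    with pytest.raises(GeneratorError, match="box too small"):
        TracerSpec(n_particles=5, diffusion_coefficient=10.0, dt=1.0,
                   n_frames=1000, box=(2.0, 2.0, 2.0)).validate()
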