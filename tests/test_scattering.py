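import numpy as np
import pytest

from assembly_ed import (
    TracerSpec,
    TrajectorySet,
    compare_isf,
    density_profile,
    generate_tracers,
    isf_from_van_hove,
    isf_self,
    q_from_inverse_angstrom,
    tracer_topology,
    van_hove_self,
)
from assembly_ed.scattering import ISFCurve, ScatteringError


@pytest.fixture(scope="module")
def brownian():
    spec = TracerSpec(n_particles=10_000, diffusion_coefficient=1e-3, dt=1.0,
                      n_frames=48, seed=2)
    return spec, generate_tracers(spec)


def test_unit_conversion():
    assert q_from_inverse_angstrom(1.26) == pytest.approx(12.6)


# -- van Hove -------------------------------------------------------------------------


def test_static_particles_all_mass_in_first_bin():
    coords = np.repeat(np.random.default_rng(0).random((1, 40, 3)), 6, axis=0)
    traj = TrajectorySet(coords, times=np.arange(6.0))
    (curve,) = van_hove_self(traj, [3.0], r_bins=np.linspace(0, 1, 21))
    occupied = np.nonzero(curve.G)[0]
    assert list(occupied) == [0]
    assert curve.normalization_integral() == pytest.approx(1.0, abs=1e-12)


def test_uniform_displacement_single_shell():
    rng = np.random.default_rng(1)
    start = rng.random((30, 3))
    d = 0.503  # not on a bin edge
    coords = np.stack([start, start + np.array([d, 0.0, 0.0])])
    traj = TrajectorySet(coords, times=np.arange(2.0))
    (curve,) = van_hove_self(traj, [1.0], r_bins=np.linspace(0, 1, 101),
                             max_origin_fraction=1.0)
    occupied = np.nonzero(curve.G)[0]
    assert occupied.size == 1
    assert abs(curve.r[occupied[0]] - d) < curve.bin_width


def test_van_hove_matches_gaussian_propagator(brownian):
    """Free diffusion: G_s(r,t) = (4 pi D t)^(-3/2) exp(-r^2 / 4 D t)."""
    spec, traj = brownian
    t = 20.0
    (curve,) = van_hove_self(traj, [t], r_bins=40)
    Dt = spec.diffusion_coefficient * t
    theory = (4 * np.pi * Dt) ** (-1.5) * np.exp(-curve.r**2 / (4 * Dt))
    shell = 4 * np.pi * curve.r**2 * curve.bin_width
    # total-variation distance between estimated and exact displacement law
    assert 0.5 * np.sum(np.abs(curve.G - theory) * shell) < 0.02
    assert curve.normalization_integral() == pytest.approx(1.0, abs=1e-3)


def test_lag_beyond_trajectory_rejected(brownian):
    _, traj = brownian
    with pytest.raises(ScatteringError, match="beyond"):
        van_hove_self(traj, [1e6])


# -- ISF ------------------------------------------------------------------------------


def test_isf_at_zero_lag_is_exactly_one(brownian):
    _, traj = brownian
    curve = isf_self(traj, q=12.6, t_grid=[0.0])
    assert curve.F[0] == 1.0


def test_single_particle_half_wavelength_displacement():
    q = 12.6
    d = np.pi / q  # q * dr = pi -> sinc term vanishes
    coords = np.zeros((2, 1, 3))
    coords[1, 0, 0] = d
    traj = TrajectorySet(coords, times=np.arange(2.0))
    curve = isf_self(traj, q, t_grid=[1.0], max_origin_fraction=1.0)
    assert curve.F[0] == pytest.approx(0.0, abs=1e-12)


def test_brownian_isf_matches_closed_form(brownian):
    """F_s(q,t) = exp(-q^2 D t) for free diffusion, within 2% for q^2 D t <= 3."""
    spec, traj = brownian
    q = q_from_inverse_angstrom(1.26)
    curve = isf_self(traj, q)
    x = q**2 * spec.diffusion_coefficient * curve.t
    keep = x <= 3.0
    assert np.max(np.abs(curve.F[keep] - np.exp(-x[keep]))) < 0.02


def test_isf_low_q_limit(brownian):
    _, traj = brownian
    curve = isf_self(traj, q=1e-4, t_grid=[0.0, 5.0, 20.0])
    assert np.all(np.abs(curve.F - 1.0) < 1e-6)


def test_isf_monotone_decay_for_free_diffusion(brownian):
    _, traj = brownian
    curve = isf_self(traj, q=12.6)
    assert np.all(np.diff(curve.F) < 0)


def test_isf_van_hove_consistency(brownian):
    """Sinc-transforming G_s reproduces F_s: two routes to the same pair."""
    _, traj = brownian
    q = 12.6
    lags = [4.0, 10.0, 20.0]
    curve = isf_self(traj, q, t_grid=lags)
    vh = van_hove_self(traj, lags, r_bins=400)
    assert np.max(np.abs(isf_from_van_hove(vh, q) - curve.F)) < 0.01


# -- comparison report ----------------------------------------------------------------


def test_compare_identical_curves_indistinguishable(brownian):
    _, traj = brownian
    c = isf_self(traj, 12.6, t_grid=[0.0, 2.0, 5.0])
    report = compare_isf(c, c)
    assert report.indistinguishable


def test_compare_analytic_exponentials():
    t = np.arange(0.0, 10.0)
    a = ISFCurve(q=1.0, t=t, F=np.exp(-2 * t), origin_stride=1, n_particles=1)
    b = ISFCurve(q=1.0, t=t, F=np.exp(-t), origin_stride=1, n_particles=1)
    report = compare_isf(a, b, threshold=0.02)
    assert report.fraction_a_below == 1.0
    assert np.all(report.sign[1:] == -1)
    # exp(-t) < 0.02 from t = 4 on; both curves are below there
    assert report.first_relaxed_lag == 4.0


def test_compare_fast_vs_slow_tracers():
    from assembly_ed.experiments import tracer_ordering_experiment

    out = tracer_ordering_experiment(seed=3, n_particles=1000)
    assert out["report"].fraction_a_below == 1.0


def test_compare_grid_mismatch_rejected():
    t = np.arange(0.0, 5.0)
    a = ISFCurve(q=1.0, t=t, F=np.exp(-t), origin_stride=1, n_particles=1)
    b = ISFCurve(q=2.0, t=t, F=np.exp(-t), origin_stride=1, n_particles=1)
    with pytest.raises(ScatteringError, match="grid"):
        compare_isf(a, b)


# -- density profiles -----------------------------------------------------------------


def test_uniform_particles_flat_profile():
    rng = np.random.default_rng(6)
    n, n_bins = 20_000, 20
    box = np.array([10.0, 10.0, 10.0])
    coords = (rng.random((1, n, 3)) * box).repeat(2, axis=0)
    traj = TrajectorySet(coords, times=np.arange(2.0), box=box)
    topo = tracer_topology(n)
    prof = density_profile(traj, topo, "z", ["protein"], n_bins=n_bins)
    rho = prof.densities["protein"]
    expected = n / box.prod()
    sigma = np.sqrt(n / n_bins) / (prof.bin_width * prof.cross_section)
    assert np.max(np.abs(rho - expected)) < 3 * sigma


def test_all_mass_in_one_plane():
    n = 100
    coords = np.zeros((1, n, 3))
    coords[0, :, 2] = 5.0
    coords[0, :, :2] = np.random.default_rng(0).random((n, 2))
    traj = TrajectorySet(coords, times=np.zeros(1), box=np.array([10.0, 10.0, 10.0]))
    prof = density_profile(traj, tracer_topology(n), "z", ["protein"], n_bins=10)
    assert (prof.densities["protein"] > 0).sum() == 1


def test_density_mass_conservation(small_sheet):
    from assembly_ed import PlantedModes, generate_trajectory
    from assembly_ed.synthetic import add_ions, default_box

    _, topology, reference = small_sheet
    box = default_box(reference, padding=3.0)
    topo2, ref2 = add_ions(topology, reference, {"ion_Mg": 50, "ion_Cl": 30}, box, seed=1)
    traj = generate_trajectory(topo2, ref2, PlantedModes(modes=[], isotropic_noise_variance=1e-4),
                               10, seed=1, box=box, solvent_diffusion=0.05)
    prof = density_profile(traj, topo2, "x", ["protein", "ion_Mg", "ion_Cl"], n_bins=17)
    for sp in ("protein", "ion_Mg", "ion_Cl"):
        assert prof.integrated_mass(sp) == pytest.approx(prof.total_mass[sp], rel=1e-6)


def test_density_unknown_species_rejected(small_sheet):
    _, topology, reference = small_sheet
    traj = TrajectorySet(reference[None], times=np.zeros(1), box=np.array([50.0, 50.0, 50.0]))
    with pytest.raises(Exception):
        density_profile(traj, topology, "z", ["species=unobtainium"])
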