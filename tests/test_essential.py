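import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import ortho_group

from assembly_ed import (
    EssentialDynamicsError,
    ModeSet,
    block_average,
    cattell_kink,
    concatenate,
    convergence_curve,
    covariance_modes,
    overlap_matrix,
    project,
    projection_histogram,
    scree,
)


# -- covariance / modes ---------------------------------------------------------------


def test_two_point_ensemble_closed_form():
    """Two rows at +-d along one direction: single eigenvalue d^2 (population)."""
    d = 0.7
    direction = np.zeros(12)
    direction[3] = 1.0
    rows = np.stack([d * direction, -d * direction])
    modes = covariance_modes(rows)
    assert modes.eigenvalues[0] == pytest.approx(d**2, rel=1e-12)
    assert np.allclose(modes.eigenvalues[1:], 0.0, atol=1e-12)
    assert abs(modes.eigenvectors[0] @ direction) == pytest.approx(1.0, abs=1e-12)


def test_gaussian_sample_recovers_generating_covariance():
    """Random 6D Gaussian at n = 1e5: eigenvalues within 3% of the truth."""
    rng = np.random.default_rng(0)
    lam_true = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
    Q = ortho_group.rvs(6, random_state=1)
    X = rng.multivariate_normal(np.zeros(6), Q @ np.diag(lam_true) @ Q.T, size=100_000)
    modes = covariance_modes(X)
    assert np.allclose(modes.eigenvalues, lam_true, rtol=0.03)
    for i in range(6):
        assert abs(modes.eigenvectors[i] @ Q[:, i]) > 0.97


def test_trace_conservation(planted_ensemble):
    ensemble, _, _ = planted_ensemble
    modes = covariance_modes(ensemble)
    per_coordinate = ensemble.rows.var(axis=0)
    assert modes.eigenvalues.sum() == pytest.approx(per_coordinate.sum(), rel=1e-6)


def test_zero_variance_ensemble_is_not_an_error():
    rows = np.ones((10, 9))
    modes = covariance_modes(rows)
    assert np.allclose(modes.eigenvalues, 0.0, atol=1e-15)


def test_eigenvector_sign_is_deterministic():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(500, 8))
    a = covariance_modes(X)
    b = covariance_modes(X[::-1].copy())
    for i in range(3):
        assert a.eigenvectors[i] @ b.eigenvectors[i] > 0.99  # same sign convention


# -- scree / kink ---------------------------------------------------------------------


def test_scree_arithmetic():
    modes = ModeSet(mean=np.zeros(3), eigenvectors=np.eye(3),
                    eigenvalues=np.array([3.0, 2.0, 1.0]), n_frames=10)
    sc = scree(modes)
    assert np.allclose(sc.fraction, [0.5, 1 / 3, 1 / 6])
    assert np.allclose(sc.accumulated, [0.5, 5 / 6, 1.0])
    assert sc.accumulated[-1] == pytest.approx(1.0, abs=1e-15)


def test_scree_equal_eigenvalues_linear_accumulation():
    modes = ModeSet(mean=np.zeros(4), eigenvectors=np.eye(4),
                    eigenvalues=np.full(4, 2.0), n_frames=10)
    sc = scree(modes)
    assert np.allclose(sc.accumulated, np.arange(1, 5) / 4)


def test_cattell_kink_step_spectrum():
    assert cattell_kink(np.array([10.0, 9.0, 8.0, 1.0, 0.9, 0.8]))[0] == 3


def test_cattell_kink_geometric_spectrum_has_none():
    lam = 0.5 ** np.arange(10)
    assert cattell_kink(lam) == []


def test_cattell_kink_on_planted_system(planted_ensemble):
    ensemble, _, planted = planted_ensemble
    modes = covariance_modes(ensemble)
    assert cattell_kink(scree(modes))[0] == len(planted.modes)


# -- projections ----------------------------------------------------------------------


def test_projection_closed_forms():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(200, 10))
    modes = covariance_modes(X)
    proj = project(X, modes, k=3)
    # ensemble-mean row projects to zero on every mode (centering)
    assert np.allclose(proj.values.mean(axis=0), 0.0, atol=1e-8)
    # mean + c*v1 projects to (c, 0, 0)
    c = 0.37
    row = (modes.mean + c * modes.eigenvectors[0])[None]
    p = (row - modes.mean) @ modes.eigenvectors[:3].T
    assert np.allclose(p, [[c, 0.0, 0.0]], atol=1e-12)


def test_projection_variance_equals_eigenvalue(planted_ensemble):
    ensemble, _, _ = planted_ensemble
    modes = covariance_modes(ensemble)
    proj = project(ensemble, modes, k=5)
    var = proj.values.var(axis=0)
    assert np.allclose(var, modes.eigenvalues[:5], rtol=1e-6)


def test_projection_label_subsetting(planted_ensemble):
    ensemble, _, _ = planted_ensemble
    modes = covariance_modes(ensemble)
    proj = project(ensemble, modes, k=2)
    plus = proj.subset(position_class="plus_end")
    assert 0 < plus.values.shape[0] < proj.values.shape[0]
    assert set(plus.labels["position_class"]) == {"plus_end"}


def test_projection_histogram_conservation_and_flags():
    rng = np.random.default_rng(4)
    px, py = rng.normal(size=2000), rng.normal(size=2000)
    hist = projection_histogram(px, py, bins=30)
    assert hist.counts.sum() == 2000  # every sample lands in a bin
    assert np.isnan(hist.log10_counts[hist.counts == 0]).all()
    assert np.allclose(hist.x_edges, -hist.x_edges[::-1])  # symmetric about 0
    # isotropic Gaussian: the fullest bin contains the origin
    imax = np.unravel_index(np.argmax(hist.counts), hist.counts.shape)
    assert hist.x_edges[imax[0]] <= 0.0 <= hist.x_edges[imax[0] + 1]
    assert hist.y_edges[imax[1]] <= 0.0 <= hist.y_edges[imax[1] + 1]


def test_projection_histogram_degenerate_input():
    px = np.zeros(50)
    hist = projection_histogram(px, px, bins=11)
    assert hist.counts.sum() == 50
    assert np.nanmax(hist.log10_counts) == pytest.approx(np.log10(50))
    assert (hist.counts > 0).sum() == 1


# -- overlaps -------------------------------------------------------------------------


def _modeset_from_vectors(V):
    return ModeSet(mean=np.zeros(V.shape[1]), eigenvectors=V,
                   eigenvalues=np.arange(V.shape[0], 0, -1, dtype=float), n_frames=10)


def test_overlap_identity_permutation_rotation():
    V = np.eye(4)
    a = _modeset_from_vectors(V)
    assert np.allclose(overlap_matrix(a, a).values, np.eye(4))
    swapped = _modeset_from_vectors(V[[1, 0, 2, 3]])
    om = overlap_matrix(a, swapped, k=2)
    assert np.allclose(om.values, [[0, 1], [1, 0]])
    theta = np.pi / 4
    rot = V.copy()
    rot[0], rot[1] = (V[0] * np.cos(theta) + V[1] * np.sin(theta),
                      -V[0] * np.sin(theta) + V[1] * np.cos(theta))
    om = overlap_matrix(a, _modeset_from_vectors(rot), k=2)
    assert np.allclose(om.values, np.sqrt(2) / 2)
    assert om.rmsip == pytest.approx(1.0)


# -- concatenation --------------------------------------------------------------------


def test_concatenate_row_count_and_provenance(planted_ensemble):
    ensemble, subunits, _ = planted_ensemble
    assert ensemble.n_rows == sum(s.n_frames for s in subunits)
    assert set(ensemble.labels["dimer_id"]) == {s.dimer_id for s in subunits}
    assert np.allclose(ensemble.mean, ensemble.rows.mean(axis=0))


def test_concatenate_rejects_signature_mismatch(planted_run):
    from assembly_ed import extract_subunit, subunit_reference

    topology, reference, _, traj = planted_run
    a = extract_subunit(traj, topology, 0, "protein")
    b = extract_subunit(traj, topology, 1, "backbone")
    with pytest.raises(EssentialDynamicsError, match="signature"):
        concatenate([a, b], subunit_reference(topology, reference))


def test_single_frame_single_subunit(planted_run):
    from assembly_ed import SubunitTrajectory, subunit_reference

    topology, reference, _, traj = planted_run
    from assembly_ed import extract_subunit

    sub = extract_subunit(traj, topology, 0, "protein")
    one = SubunitTrajectory(dimer_id=0, coordinates=sub.coordinates[:1],
                            atom_ids=sub.atom_ids, selection=sub.selection,
                            times=sub.times[:1], ordering_signature=sub.ordering_signature)
    ens = concatenate([one], subunit_reference(topology, reference), reference_mode="fixed")
    assert ens.n_rows == 1
    assert np.allclose(ens.mean, ens.rows[0])


# -- convergence ----------------------------------------------------------------------


def test_convergence_deterministic_system_overlap_one():
    """Noise-free planted system: any disjoint subsets give identical first modes."""
    rng = np.random.default_rng(5)
    direction = rng.normal(size=20)
    direction /= np.linalg.norm(direction)
    blocks = [np.outer(rng.normal(0, 1.0, 50), direction) for _ in range(8)]
    curve = convergence_curve(blocks, [1, 4], replicates=5, seed=0)
    assert np.allclose(curve.overlaps, 1.0, atol=1e-9)


def test_convergence_rejects_oversized_subsets():
    blocks = [np.random.default_rng(i).normal(size=(10, 6)) for i in range(4)]
    with pytest.raises(EssentialDynamicsError, match="too large"):
        convergence_curve(blocks, [3], replicates=2, seed=0)


# -- block averaging ------------------------------------------------------------------


@pytest.mark.parametrize(
    "series, block, expected",
    [
        ([1.0, 2.0, 3.0, 4.0], 2, [1.5, 3.5]),
        ([1.0, 2.0, 3.0, 4.0, 5.0], 2, [1.5, 3.5, 5.0]),  # trailing partial as-is
        ([7.0, 7.0, 7.0], 1, [7.0, 7.0, 7.0]),
    ],
)
def test_block_average_examples(series, block, expected):
    assert np.allclose(block_average(np.array(series), block), expected)


def test_block_average_constant_series_2d():
    x = np.full((10, 3), 2.5)
    out = block_average(x, 4)
    assert out.shape == (3, 3)
    assert np.allclose(out, 2.5)
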