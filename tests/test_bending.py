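import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from assembly_ed import (
    BendSegment,
    PlantedModes,
    bending_angle,
    bending_series,
    dimer_axis,
    generate_trajectory,
    monomer_com,
)
from assembly_ed.bending import BendingError


def test_monomer_com_closed_forms(small_sheet):
    _, topology, reference = small_sheet
    ids = topology.monomer_atoms(0)
    # unit masses: COM is the plain mean
    assert np.allclose(monomer_com(reference, topology, 0), reference[ids].mean(axis=0))
    # explicit weights (1, 3, 0...) pull toward the heavy atom
    frame = reference.copy()
    frame[ids[0]] = [0.0, 0.0, 0.0]
    frame[ids[1]] = [4.0, 0.0, 0.0]
    w = np.zeros(ids.size)
    w[0], w[1] = 1.0, 3.0
    assert np.allclose(monomer_com(frame, topology, 0, weights=w), [3.0, 0.0, 0.0])
    with pytest.raises(BendingError, match="mass"):
        monomer_com(frame, topology, 0, weights=np.zeros(ids.size))


def test_dimer_axis_points_alpha_to_beta(small_sheet):
    _, topology, reference = small_sheet
    for d in (0, 4, 8):
        axis = dimer_axis(reference, topology, d)
        assert np.linalg.norm(axis) == pytest.approx(1.0)
        assert axis[2] > 0.99  # straight lattice: alpha -> beta points to +z (plus end)


@pytest.mark.parametrize(
    "u, v, expected",
    [
        ((0, 0, 1), (0, 0, 1), 0.0),
        ((0, 0, 1), (0, 1 / np.sqrt(2), 1 / np.sqrt(2)), 45.0),
        ((0, 0, 1), (0, 0, -1), 180.0),
    ],
)
def test_bending_angle_closed_forms(u, v, expected):
    assert bending_angle(np.array(u, float), np.array(v, float)) == pytest.approx(expected, abs=1e-9)
    assert bending_angle(np.array(v, float), np.array(u, float)) == pytest.approx(expected, abs=1e-9)


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 10_000))
def test_angles_invariant_under_global_rigid_transform(small_sheet, seed):
    # a genuinely bent configuration: arccos is well-conditioned away from 0
    _, topology, reference = small_sheet
    plan = [BendSegment(pf_id=p, dimer_layers=(0, 2), target_angle_deg=9.0) for p in range(3)]
    bent = generate_trajectory(topology, reference, PlantedModes(modes=[], bend_plan=plan),
                               1, seed=0).coordinates[0]
    rng = np.random.default_rng(seed)
    R = Rotation.from_rotvec(rng.normal(0, 1, 3)).as_matrix()
    t = rng.normal(0, 10, 3)
    from assembly_ed import TrajectorySet

    base = TrajectorySet(bent[None], times=np.zeros(1))
    moved = TrajectorySet((bent @ R.T + t)[None], times=np.zeros(1))
    rec_a, _ = bending_series(base, topology)
    rec_b, _ = bending_series(moved, topology)
    assert np.max(np.abs(rec_a["angle_deg"].to_numpy() - rec_b["angle_deg"].to_numpy())) <= 1e-9


def test_straight_lattice_zero_angles(small_sheet):
    from assembly_ed import TrajectorySet

    _, topology, reference = small_sheet
    traj = TrajectorySet(np.repeat(reference[None], 3, axis=0), times=np.arange(3.0))
    records, summary = bending_series(traj, topology)
    assert np.max(records["angle_deg"]) < 1e-6
    assert summary.stats["count"].sum() == len(records)


def test_pair_classes_cover_the_sheet(small_sheet):
    from assembly_ed import TrajectorySet

    _, topology, reference = small_sheet
    traj = TrajectorySet(reference[None], times=np.zeros(1))
    records, summary = bending_series(traj, topology)
    # 3 PFs x 2 adjacent pairs: one plus-facing and one minus-facing pair per PF
    assert len(records) == 6
    counts = records.groupby("pair_class").size().to_dict()
    assert counts == {"plus_vs_central": 3, "minus_vs_central": 3}
    assert sum(h.sum() for h in summary.histograms.values()) == len(records)


def test_imposed_bend_class_means(small_sheet):
    _, topology, reference = small_sheet
    plan = [BendSegment(pf_id=p, dimer_layers=(2, 2), target_angle_deg=11.0) for p in range(3)]
    planted = PlantedModes(modes=[], bend_plan=plan)
    traj = generate_trajectory(topology, reference, planted, 5, seed=0)
    _, summary = bending_series(traj, topology)
    assert summary.class_mean("plus_vs_central") == pytest.approx(11.0, abs=0.5)
    assert summary.class_mean("minus_vs_central") == pytest.approx(0.0, abs=1e-6)


def test_noisy_bend_recovery_unbiased(small_sheet):
    _, topology, reference = small_sheet
    plan = [BendSegment(pf_id=p, dimer_layers=(0, 2), target_angle_deg=4.0) for p in range(3)]
    planted = PlantedModes(modes=[], isotropic_noise_variance=4e-4, bend_plan=plan)
    traj = generate_trajectory(topology, reference, planted, 300, seed=8)
    records, _ = bending_series(traj, topology)
    ang = records["angle_deg"].to_numpy()
    se = ang.std() / np.sqrt(ang.size)
    assert abs(ang.mean() - 4.0) < 3 * se + 0.05  # small convexity allowance at tiny noise


def test_intra_dimer_variant_straight_lattice(small_sheet):
    from assembly_ed import TrajectorySet

    _, topology, reference = small_sheet
    traj = TrajectorySet(reference[None], times=np.zeros(1))
    records, _ = bending_series(traj, topology, variant="intra_dimer")
    assert len(records) == topology.n_dimers
    # both half-axes of a straight dimer point along +z: angles ~ 0
    assert np.max(records["angle_deg"]) < 1e-6


def test_ramped_bend_reaches_target(small_sheet):
    _, topology, reference = small_sheet
    plan = [BendSegment(pf_id=0, dimer_layers=(2, 2), target_angle_deg=10.0, ramp_frames=10)]
    planted = PlantedModes(modes=[], bend_plan=plan)
    traj = generate_trajectory(topology, reference, planted, 20, seed=0)
    records, _ = bending_series(traj, topology)
    bent = records[(records["pf"] == 0) & (records["pair_class"] == "plus_vs_central")]
    assert bent["angle_deg"].iloc[0] == pytest.approx(0.0, abs=1e-9)
    assert bent[bent["time"] >= 100.0]["angle_deg"].min() == pytest.approx(10.0, abs=1e-9)
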