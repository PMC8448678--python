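"""Generate a planted-mode demonstration trajectory and verify determinism.

Writes a compact sheet trajectory (300 frames, 8 atoms per monomer) in the
multi-frame XYZ exchange format so the downstream file-based tools have a
real input, and records the planted ground truth (mode variances, noise
level) in the manifest.  The heavier production-size runs used by the later
analyses are regenerated in memory by those scripts from the same seeds.
"""

import sys
from pathlib import Path

import numpy as np

from assembly_ed import generate_trajectory, make_planted_modes, subunit_reference
from assembly_ed.experiments import sheet_spec
from assembly_ed.synthetic import build_lattice, export_system

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    spec = sheet_spec(atoms_per_monomer=8, seed=seed)
    topology, reference = build_lattice(spec)
    template = subunit_reference(topology, reference)
    planted = make_planted_modes(template, (0.15, 0.10, 0.08), total_variance=0.03, seed=seed)
    traj = generate_trajectory(topology, reference, planted, n_frames=300, seed=seed)
    again = generate_trajectory(topology, reference, planted, n_frames=300, seed=seed)
    assert np.array_equal(traj.coordinates, again.coordinates), "seed determinism violated"

    export_system(
        RESULTS / "demo_sheet", topology, reference, trajectory=traj,
        lattice=spec, seed=seed,
        planted={
            "variances_nm2": [m.variance for m in planted.modes],
            "labels": [m.label for m in planted.modes],
            "isotropic_noise_variance_nm2": planted.isotropic_noise_variance,
        },
    )
    print(f"wrote {RESULTS / 'demo_sheet'}: {traj.n_frames} frames x {traj.n_atoms} atoms, "
          f"dt = {traj.dt} ps, planted mode variances "
          f"{[round(m.variance, 5) for m in planted.modes]} nm^2 "
          f"(bit-identical regeneration confirmed)")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
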