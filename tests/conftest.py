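import numpy as np
import pytest

from assembly_ed import (
    LatticeSpec,
    build_lattice,
    concatenate,
    extract_subunit,
    generate_trajectory,
    make_planted_modes,
    subunit_reference,
)


@pytest.fixture(scope="session")
def small_sheet():
    """3x3-heterodimer sheet with 8 atoms per monomer (9 dimers, 144 atoms)."""
    spec = LatticeSpec(n_protofilaments=3, n_layers=6, geometry="sheet",
                       atoms_per_monomer=8, seed=0)
    topology, reference = build_lattice(spec)
    return spec, topology, reference


@pytest.fixture(scope="session")
def planted_run(small_sheet):
    """Sheet trajectory with three planted modes at fractions 0.15/0.10/0.08."""
    _, topology, reference = small_sheet
    template = subunit_reference(topology, reference)
    planted = make_planted_modes(template, (0.15, 0.10, 0.08), total_variance=0.03, seed=3)
    traj = generate_trajectory(topology, reference, planted, n_frames=800, seed=3)
    return topology, reference, planted, traj


@pytest.fixture(scope="session")
def planted_ensemble(planted_run):
    """Concatenated, superposed subunit ensemble of the planted sheet run."""
    topology, reference, planted, traj = planted_run
    subunits = [
        extract_subunit(traj, topology, d, "protein")
        for d in sorted(int(i) for i in topology.dimers["id"])
    ]
    template = subunit_reference(topology, reference)
    ensemble = concatenate(subunits, template, topology=topology, system="sheet")
    return ensemble, subunits, planted
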