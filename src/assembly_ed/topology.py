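"""Assembly topologies: atom tables, grouping hierarchy, species and selections.

An :class:`AssemblyTopology` describes a tubulin-like assembly as three linked
tables: atoms, monomers and heterodimers.  The hierarchy is

    atom -> monomer -> dimer -> protofilament / layer / position class

Ions and water do not belong to any monomer; they are attached to a reserved
"solvent" group (monomer id ``SOLVENT_GROUP``).  Coordinates are *not* stored
here -- a topology is pure bookkeeping and all selections are pure functions
of it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SPECIES = (
    "protein",
    "ion_Mg",
    "ion_Cl",
    "water",
    "nucleotide_GTP",
    "nucleotide_GDP",
)

POSITION_CLASSES = (
    "plus_end",
    "central",
    "minus_end",
    "plus_corner",
    "minus_corner",
    "body",
)

#: reserved monomer id for atoms outside the protein hierarchy (ions, water)
SOLVENT_GROUP = -1

_ATOM_COLS = ["id", "name", "mass", "species", "backbone", "calpha", "monomer"]
_MONOMER_COLS = ["id", "dimer", "label"]
_DIMER_COLS = ["id", "pf", "layer", "position_class"]


class TopologyError(ValueError):
    """Raised for inconsistent or malformed topologies."""


@dataclass
class AssemblyTopology:
    """Atom table plus grouping hierarchy.

    Parameters
    ----------
    atoms
        One row per atom: ``id`` (0..n-1, equal to row position), ``name``,
        ``mass`` (amu), ``species`` (one of :data:`SPECIES`), ``backbone`` and
        ``calpha`` flags, ``monomer`` id (:data:`SOLVENT_GROUP` for solvent).
    monomers
        One row per monomer: ``id``, parent ``dimer`` id, ``label``
        (``"alpha"`` or ``"beta"``).
    dimers
        One row per heterodimer: ``id``, ``pf`` (protofilament index),
        ``layer`` (dimer-layer index along the filament axis, 0 at the minus
        end) and ``position_class``.
    """

    atoms: pd.DataFrame
    monomers: pd.DataFrame
    dimers: pd.DataFrame

    # -- construction / validation ------------------------------------------------

    def __post_init__(self) -> None:
        self.atoms = self.atoms[_ATOM_COLS].reset_index(drop=True)
        self.monomers = self.monomers[_MONOMER_COLS].reset_index(drop=True)
        self.dimers = self.dimers[_DIMER_COLS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        if len(self.atoms) == 0:
            raise TopologyError("empty atom table")
        ids = self.atoms["id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise TopologyError("atom ids must be 0..n-1 in row order")
        bad = set(self.atoms["species"]) - set(SPECIES)
        if bad:
            raise TopologyError(f"unknown species labels: {sorted(bad)}")
        bad = set(self.dimers["position_class"]) - set(POSITION_CLASSES)
        if bad:
            raise TopologyError(f"unknown position classes: {sorted(bad)}")
        # calpha subset of backbone subset of protein
        a = self.atoms
        if (a["calpha"] & ~a["backbone"]).any():
            raise TopologyError("calpha atoms must be backbone atoms")
        if (a["backbone"] & (a["species"] != "protein")).any():
            raise TopologyError("backbone atoms must be protein atoms")
        # every non-solvent atom belongs to exactly one known monomer
        mono_ids = set(self.monomers["id"])
        referenced = set(a.loc[a["monomer"] != SOLVENT_GROUP, "monomer"])
        if not referenced <= mono_ids:
            raise TopologyError("atom references unknown monomer")
        # each dimer has exactly two monomers, one alpha + one beta
        for dimer_id, grp in self.monomers.groupby("dimer"):
            if len(grp) != 2 or set(grp["label"]) != {"alpha", "beta"}:
                raise TopologyError(
                    f"dimer {dimer_id} must have exactly one alpha and one beta monomer"
                )
        if not set(self.monomers["dimer"]) <= set(self.dimers["id"]):
            raise TopologyError("monomer references unknown dimer")

    # -- sizes --------------------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_monomers(self) -> int:
        return len(self.monomers)

    @property
    def n_dimers(self) -> int:
        return len(self.dimers)

    @property
    def masses(self) -> np.ndarray:
        return self.atoms["mass"].to_numpy(float)

    # -- hierarchy lookups --------------------------------------------------------

    def monomer_atoms(self, monomer_id: int) -> np.ndarray:
        """Atom ids of one monomer, sorted by id."""
        out = self.atoms.loc[self.atoms["monomer"] == monomer_id, "id"].to_numpy()
        if out.size == 0:
            raise TopologyError(f"monomer {monomer_id} has no atoms")
        return np.sort(out)

    def dimer_monomers(self, dimer_id: int) -> tuple[int, int]:
        """(alpha monomer id, beta monomer id) of a dimer."""
        grp = self.monomers[self.monomers["dimer"] == dimer_id]
        if len(grp) != 2:
            raise TopologyError(f"unknown dimer {dimer_id}")
        alpha = int(grp.loc[grp["label"] == "alpha", "id"].iloc[0])
        beta = int(grp.loc[grp["label"] == "beta", "id"].iloc[0])
        return alpha, beta

    def dimer_atoms(self, dimer_id: int) -> np.ndarray:
        """Atom ids of one dimer in canonical order: alpha atoms then beta atoms, each by id."""
        alpha, beta = self.dimer_monomers(dimer_id)
        return np.concatenate([self.monomer_atoms(alpha), self.monomer_atoms(beta)])

    def position_class(self, dimer_id: int) -> str:
        row = self.dimers[self.dimers["id"] == dimer_id]
        if row.empty:
            raise TopologyError(f"unknown dimer {dimer_id}")
        return str(row["position_class"].iloc[0])

    def pf_dimers(self, pf_id: int) -> list[int]:
        """Dimer ids of one protofilament ordered by layer (minus to plus end)."""
        grp = self.dimers[self.dimers["pf"] == pf_id].sort_values("layer")
        return [int(i) for i in grp["id"]]

    @property
    def protofilaments(self) -> list[int]:
        return sorted(int(p) for p in self.dimers["pf"].unique())

    # -- selections ---------------------------------------------------------------

    def select(self, selector: str) -> np.ndarray:
        """Resolve a named atom selection to a sorted atom-id array.

        Known selectors: ``backbone``, ``calpha``, ``protein``, ``sidechain``
        (protein minus backbone), ``all`` and ``species=<label>``.
        """
        a = self.atoms
        if selector == "all":
            mask = np.ones(len(a), dtype=bool)
        elif selector == "protein":
            mask = (a["species"] == "protein").to_numpy()
        elif selector == "backbone":
            mask = a["backbone"].to_numpy(bool)
        elif selector == "calpha":
            mask = a["calpha"].to_numpy(bool)
        elif selector == "sidechain":
            mask = (a["species"] == "protein").to_numpy() & ~a["backbone"].to_numpy(bool)
        elif selector.startswith("species="):
            label = selector.split("=", 1)[1]
            if label not in SPECIES:
                raise TopologyError(f"unknown species label {label!r}")
            mask = (a["species"] == label).to_numpy()
        else:
            raise TopologyError(f"unknown selector {selector!r}")
        return np.sort(a.loc[mask, "id"].to_numpy())

    # -- equality (round-trip contract) -------------------------------------------

    def equals(self, other: "AssemblyTopology") -> bool:
        return (
            self.atoms.equals(other.atoms)
            and self.monomers.equals(other.monomers)
            and self.dimers.equals(other.dimers)
        )


# -- JSON assembly map ----------------------------------------------------------------


def write_topology(topology: AssemblyTopology, path: str | Path) -> None:
    """Write the full topology as a JSON assembly map (lossless)."""
    payload = {
        "format": "assembly-map/1",
        "atoms": topology.atoms.to_dict(orient="list"),
        "monomers": topology.monomers.to_dict(orient="list"),
        "dimers": topology.dimers.to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(payload))


def read_topology(path: str | Path, pdb_path: str | Path | None = None):
    """Read a topology from a JSON assembly map.

    If ``pdb_path`` is given, reference coordinates (nm) are read from the PDB
    and returned alongside; an atom-count mismatch between the two files is an
    error.  Returns ``topology`` or ``(topology, coordinates)``.
    """
    payload = json.loads(Path(path).read_text())
    topology = AssemblyTopology(
        atoms=pd.DataFrame(payload["atoms"]),
        monomers=pd.DataFrame(payload["monomers"]),
        dimers=pd.DataFrame(payload["dimers"]),
    )
    if pdb_path is None:
        return topology
    coords = read_pdb_coordinates(pdb_path)
    if coords.shape[0] != topology.n_atoms:
        raise TopologyError(
            f"PDB atom count {coords.shape[0]} does not match assembly map "
            f"({topology.n_atoms} atoms)"
        )
    return topology, coords


# -- PDB export (visualization view; biotite does the format work) --------------------

_PDB_ELEMENT = {
    "protein": "C",
    "ion_Mg": "MG",
    "ion_Cl": "CL",
    "water": "O",
    "nucleotide_GTP": "P",
    "nucleotide_GDP": "P",
}


def write_pdb(topology: AssemblyTopology, coordinates_nm: np.ndarray, path: str | Path) -> None:
    """Export atoms + one coordinate set as PDB (coordinates converted nm -> A)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = topology.n_atoms
    coords = np.asarray(coordinates_nm, float)
    if coords.shape != (n, 3):
        raise TopologyError(f"coordinate shape {coords.shape} != ({n}, 3)")
    arr = struc.AtomArray(n)
    arr.coord = coords * 10.0
    a = topology.atoms
    res_ids = a["monomer"].to_numpy().copy()
    res_ids[res_ids == SOLVENT_GROUP] = topology.n_monomers  # solvent as trailing residue
    arr.res_id = res_ids + 1
    arr.res_name = np.where(a["species"] == "protein", "TUB", "HET")
    arr.atom_name = [str(s)[:4] for s in a["name"]]
    arr.element = [_PDB_ELEMENT[s] for s in a["species"]]
    arr.chain_id = np.full(n, "A")
    arr.hetero = (a["species"] != "protein").to_numpy()
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_pdb_coordinates(path: str | Path) -> np.ndarray:
    """Read coordinates (nm) from a PDB file, in file order."""
    from biotite.structure.io.pdb import PDBFile

    arr = PDBFile.read(str(path)).get_structure(model=1)
    return np.asarray(arr.coord, float) / 10.0
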