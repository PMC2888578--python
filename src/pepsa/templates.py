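"""Residue templates: ideal heavy-atom geometry and bonded topology.

Templates come from the chemical component dictionary bundled with
biotite, reduced to heavy atoms (the force field is an extended-atom
model: hydrogens are subsumed into their parent heavy atoms, see
docs/methods.md).  Phosphotyrosine (PTR) and the acetyl/N-methylamide
capping groups (ACE, NME) are first-class residues.  A handful of
single-bead pseudo-residues used by the synthetic rigid scaffold are
defined locally.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "ResidueTemplate",
    "get_template",
    "is_known_residue",
    "KNOWN_RESIDUES",
    "AMINO_ACIDS",
    "BACKBONE_ATOMS",
    "ELEMENT_MASSES",
    "UnknownResidueError",
]

AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL PTR".split()
)
CAPS = frozenset({"ACE", "NME"})
#: single-atom pseudo-residues for the synthetic rigid scaffold:
#: apolar pocket bead, cationic site, anionic/polar site
SCAFFOLD_BEADS = frozenset({"SCB", "SCP", "SCN"})
KNOWN_RESIDUES = AMINO_ACIDS | CAPS | SCAFFOLD_BEADS

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Extended-atom masses: parent heavy atom plus its implicit hydrogens are
# lumped together only in the Lennard-Jones radii; masses stay elemental
# (the factor-of-~1.1 difference is irrelevant for conformational sampling).
ELEMENT_MASSES = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
}


class UnknownResidueError(ValueError):
    """Raised when a residue name has no template."""


@dataclass(frozen=True)
class ResidueTemplate:
    name: str
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_heavy, 3) ideal geometry, Å
    bonds: tuple[tuple[str, str], ...]  # intra-residue heavy-atom bonds

    @property
    def heavy_sidechain(self) -> tuple[str, ...]:
        """Side-chain heavy atoms (everything beyond N, CA, C, O)."""
        return tuple(n for n in self.atom_names if n not in BACKBONE_ATOMS)

    def index(self, atom_name: str) -> int:
        return self.atom_names.index(atom_name)


_BEAD_DEFS = {
    "SCB": ("C1", "C"),
    "SCP": ("N1", "N"),
    "SCN": ("O1", "O"),
}


@lru_cache(maxsize=None)
def get_template(residue_name: str) -> ResidueTemplate:
    """Return the heavy-atom template for a residue.

    Raises :class:`UnknownResidueError` for residue names absent from the
    registry — the caller is expected to surface the offending name.
    """
    residue_name = residue_name.upper()
    if residue_name in _BEAD_DEFS:
        atom, element = _BEAD_DEFS[residue_name]
        return ResidueTemplate(
            name=residue_name,
            atom_names=(atom,),
            elements=(element,),
            coords=np.zeros((1, 3)),
            bonds=(),
        )
    if residue_name not in KNOWN_RESIDUES:
        raise UnknownResidueError(f"no template for residue '{residue_name}'")

    import biotite.structure.info as struc_info

    component = struc_info.residue(residue_name)
    heavy = component.element != "H"
    # Drop the free-terminus oxygen: chains are either peptide-bonded or
    # capped, so OXT never appears in a built model.
    heavy &= component.atom_name != "OXT"
    atoms = component[heavy]
    names = [str(n) for n in atoms.atom_name]
    if residue_name == "NME" and "CH3" not in names:
        # CCD names the N-methyl carbon plain "C"; rename to the PDB
        # convention so it cannot be confused with a backbone carbonyl.
        names = ["CH3" if n == "C" else n for n in names]

    name_of_index = {}
    for i, orig_idx in enumerate(np.where(heavy)[0]):
        name_of_index[int(orig_idx)] = names[i]
    bonds = []
    for i, j, _ in component.bonds.as_array():
        if int(i) in name_of_index and int(j) in name_of_index:
            bonds.append((name_of_index[int(i)], name_of_index[int(j)]))

    return ResidueTemplate(
        name=residue_name,
        atom_names=tuple(names),
        elements=tuple(str(e) for e in atoms.element),
        coords=np.array(atoms.coord, dtype=float),
        bonds=tuple(bonds),
    )


def is_known_residue(residue_name: str) -> bool:
    return residue_name.upper() in KNOWN_RESIDUES
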