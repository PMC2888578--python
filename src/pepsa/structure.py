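"""Peptide–scaffold complex models: PDB I/O, capping, mutation, mobility.

The central container is :class:`ComplexModel`: an ordered list of heavy
atoms partitioned into a *peptide* (the phosphopeptide ligand, possibly
ACE/NME-capped) and a *scaffold* (the rigid SH2 domain or a synthetic
mock receptor).  Every atom carries exactly one mobility label:

``free``
    integrated normally — the peptide residues C-terminal to the
    phosphotyrosine anchor;
``restrained``
    tethered to a reference position by a harmonic restraint — the
    phosphotyrosine itself (and anything N-terminal to it);
``frozen``
    never moved — the scaffold.

All coordinates are Å; residue indices are 1-based and global over the
model in atom order.
"""

from __future__ import annotations

import copy as _copy
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np

from .geometry import apply_transform, dihedral_angle, kabsch, place_atom
from .templates import (
    AMINO_ACIDS,
    BACKBONE_ATOMS,
    ELEMENT_MASSES,
    KNOWN_RESIDUES,
    UnknownResidueError,
    get_template,
)

__all__ = [
    "Mobility",
    "AtomRecord",
    "ComplexModel",
    "SpecificitySegment",
    "read_pdb",
    "write_pdb",
    "write_ensemble_pdb",
    "cap_termini",
    "mutate_residue",
    "assign_mobility",
    "specificity_segment",
    "PDBParseError",
    "ModelError",
    "UnsupportedMutationError",
    "MobilitySchemeError",
]

DEG = np.pi / 180.0


class PDBParseError(ValueError):
    pass


class ModelError(ValueError):
    pass


class UnsupportedMutationError(ValueError):
    pass


class MobilitySchemeError(ValueError):
    pass


class Mobility(IntEnum):
    FREE = 0
    RESTRAINED = 1
    FROZEN = 2


@dataclass(eq=False)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    charge: float = 0.0
    mass: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ModelError(f"non-finite position for atom {self.name}")
        if self.mass == 0.0:
            self.mass = ELEMENT_MASSES.get(self.element.upper(), 12.011)
        if self.mass <= 0:
            raise ModelError(f"non-positive mass for atom {self.name}")


@dataclass(eq=False)
class ComplexModel:
    """Ordered heavy-atom model of a peptide bound to a rigid scaffold."""

    atoms: list[AtomRecord]
    peptide_residues: list[int] = field(default_factory=list)
    scaffold_residues: list[int] = field(default_factory=list)
    mobility: np.ndarray | None = None  # per-atom Mobility, set by assign_mobility
    reference_positions: np.ndarray | None = None  # restraint anchors, Å
    needs_minimization: bool = False
    atom_types: list[str] | None = None  # force-field types, set by charge assignment

    # -- array views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected ({self.n_atoms}, 3) coordinates")
        for atom, xyz in zip(self.atoms, coords):
            atom.position = xyz.copy()

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    # -- residue bookkeeping -----------------------------------------
    def residue_indices(self) -> list[int]:
        seen: list[int] = []
        for a in self.atoms:
            if not seen or a.residue_index != seen[-1]:
                seen.append(a.residue_index)
        return seen

    def residue_name(self, residue_index: int) -> str:
        for a in self.atoms:
            if a.residue_index == residue_index:
                return a.residue_name
        raise KeyError(f"no residue with index {residue_index}")

    def atoms_of_residue(self, residue_index: int) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.residue_index == residue_index]

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.residue_index == residue_index and a.name == atom_name:
                return i
        raise KeyError(f"atom {atom_name} not found in residue {residue_index}")

    def find_ptyr(self) -> int | None:
        """Residue index of the phosphotyrosine anchor, if present."""
        for a in self.atoms:
            if a.residue_name == "PTR" and a.residue_index in self.peptide_residues:
                return a.residue_index
        return None

    def copy(self) -> "ComplexModel":
        return _copy.deepcopy(self)

    def validate(self) -> None:
        """Check the model invariants; raise :class:`ModelError` on violation."""
        if set(self.peptide_residues) & set(self.scaffold_residues):
            raise ModelError("peptide and scaffold residue sets overlap")
        for ri in self.residue_indices():
            names = [self.atoms[i].name for i in self.atoms_of_residue(ri)]
            if len(names) != len(set(names)):
                raise ModelError(f"duplicate atom names in residue {ri}")
        if not np.all(np.isfinite(self.coords)):
            raise ModelError("non-finite coordinates")
        if self.mobility is not None:
            if len(self.mobility) != self.n_atoms:
                raise ModelError("mobility mask length mismatch")
            restrained = np.asarray(self.mobility) == Mobility.RESTRAINED
            if restrained.any() and self.reference_positions is None:
                raise ModelError("restrained atoms lack reference positions")


@dataclass(frozen=True)
class SpecificitySegment:
    """Residue indices of the pTyr+1..pTyr+3 (optionally +4) positions."""

    residue_indices: tuple[int, ...]

    def __post_init__(self):
        idx = self.residue_indices
        if len(idx) not in (3, 4) or any(b - a != 1 for a, b in zip(idx, idx[1:])):
            raise ValueError("specificity segment must be 3-4 consecutive residues")


def specificity_segment(model: ComplexModel, length: int = 3) -> SpecificitySegment:
    """Locate the specificity-determining segment C-terminal to the pTyr."""
    ptyr = model.find_ptyr()
    if ptyr is None:
        raise ModelError("model has no phosphotyrosine residue")
    idx = []
    for k in range(1, length + 1):
        ri = ptyr + k
        if ri not in model.peptide_residues or model.residue_name(ri) in ("NME",):
            break
        idx.append(ri)
    if len(idx) < 3:
        raise ModelError("fewer than 3 peptide residues C-terminal to the pTyr")
    return SpecificitySegment(tuple(idx))


# ---------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------

def _prevalidate_pdb_lines(lines: list[str]) -> None:
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"line {lineno}: truncated coordinate record")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise PDBParseError(f"line {lineno}: malformed coordinate fields") from None


def read_pdb(path, peptide_chain: str | None = None) -> ComplexModel:
    """Read a peptide–scaffold complex from a PDB file.

    Hydrogens are discarded (extended-atom model).  Residues without a
    template are rejected with an error naming the residue.  The peptide
    is taken to be the chain containing the phosphotyrosine (PTR) unless
    ``peptide_chain`` is given explicitly; all other residues form the
    scaffold.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    lines = path.read_text().splitlines()
    _prevalidate_pdb_lines(lines)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        array = pdb_file.get_structure(model=1)
    except Exception as exc:  # biotite raises various subclasses
        raise PDBParseError(f"{path.name}: {exc}") from exc

    array = array[array.element != "H"]

    atoms: list[AtomRecord] = []
    residue_key_to_index: dict[tuple, int] = {}
    index_to_chain: dict[int, str] = {}
    index_to_name: dict[int, str] = {}
    for i in range(array.array_length()):
        res_name = str(array.res_name[i]).upper()
        if res_name not in KNOWN_RESIDUES:
            raise UnknownResidueError(
                f"unknown residue '{res_name}' at chain {array.chain_id[i]} "
                f"{array.res_id[i]} (no template available)"
            )
        key = (str(array.chain_id[i]), int(array.res_id[i]), res_name)
        if key not in residue_key_to_index:
            residue_key_to_index[key] = len(residue_key_to_index) + 1
        ri = residue_key_to_index[key]
        index_to_chain[ri] = str(array.chain_id[i])
        index_to_name[ri] = res_name
        atoms.append(
            AtomRecord(
                serial=len(atoms) + 1,
                name=str(array.atom_name[i]),
                element=str(array.element[i]),
                residue_index=ri,
                residue_name=res_name,
                chain_id=str(array.chain_id[i]),
                position=np.array(array.coord[i], dtype=float),
            )
        )

    # required backbone atoms for amino-acid residues
    by_res: dict[int, set] = {}
    for a in atoms:
        by_res.setdefault(a.residue_index, set()).add(a.name)
    for ri, names in by_res.items():
        if index_to_name[ri] in AMINO_ACIDS:
            missing = {"N", "CA", "C"} - names
            if missing:
                raise ModelError(
                    f"residue {ri} ({index_to_name[ri]}) missing backbone atoms: "
                    + ", ".join(sorted(missing))
                )

    if peptide_chain is None:
        ptyr_chains = {a.chain_id for a in atoms if a.residue_name == "PTR"}
        peptide_chain = next(iter(sorted(ptyr_chains)), None)
    peptide, scaffold = [], []
    for ri in sorted(by_res):
        (peptide if index_to_chain[ri] == peptide_chain else scaffold).append(ri)

    return ComplexModel(atoms=atoms, peptide_residues=peptide, scaffold_residues=scaffold)


def _to_atom_array(model: ComplexModel, coords: np.ndarray):
    import biotite.structure as struc

    n = model.n_atoms
    array = struc.AtomArray(n)
    array.coord = np.asarray(coords, dtype=float)
    array.chain_id = np.array([a.chain_id for a in model.atoms])
    array.res_id = np.array([a.residue_index for a in model.atoms])
    array.res_name = np.array([a.residue_name for a in model.atoms])
    array.atom_name = np.array([a.name for a in model.atoms])
    array.element = np.array([a.element for a in model.atoms])
    array.hetero = np.array(
        [a.residue_name not in AMINO_ACIDS or a.residue_name == "PTR" for a in model.atoms]
    )
    return array


def write_pdb(model: ComplexModel, path, multi_model: bool = False) -> None:
    """Write a single-conformer model; ``multi_model`` wraps it in MODEL/ENDMDL."""
    coords = model.coords[np.newaxis] if multi_model else model.coords
    _write_coords(model, coords, path)


def write_ensemble_pdb(model: ComplexModel, coord_sets: np.ndarray, path) -> None:
    """Write an ensemble of conformers of one model as a multi-model PDB."""
    coord_sets = np.asarray(coord_sets, dtype=float)
    if coord_sets.ndim != 3:
        raise ValueError("coord_sets must have shape (n_models, n_atoms, 3)")
    _write_coords(model, coord_sets, path)


def read_ensemble_pdb(path, peptide_chain: str | None = None):
    """Read a multi-model PDB as ``(model, coords_stack)``.

    The first model supplies the topology; the stack holds one
    coordinate set per MODEL block, shape ``(n_models, n_atoms, 3)``.
    """
    import biotite.structure.io.pdb as pdb

    base = read_pdb(path, peptide_chain=peptide_chain)
    pdb_file = pdb.PDBFile.read(str(Path(path)))
    stack = pdb_file.get_structure()
    stack = stack[..., stack.element != "H"]
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[np.newaxis]
    return base, coords


def _write_coords(model: ComplexModel, coords: np.ndarray, path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if model.n_atoms > 99999:
        raise ModelError("more than 99999 atoms: PDB serial field overflow")
    if coords.ndim == 3:
        stack = struc.stack([_to_atom_array(model, c) for c in coords])
        to_write = stack
    else:
        to_write = _to_atom_array(model, coords)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(to_write)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------
# Capping
# ---------------------------------------------------------------------

_AMIDE_C_N = 1.335
_C_O = 1.229
_C_CH3 = 1.522
_N_CH3 = 1.449


def cap_termini(model: ComplexModel) -> ComplexModel:
    """Neutralize the peptide termini with ACE and NME blocking groups.

    The caps are grown from ideal amide geometry off the existing
    backbone.  Already-capped peptides pass through unchanged with a
    warning.  Residues are renumbered sequentially afterwards.
    """
    model = model.copy()
    if not model.peptide_residues:
        raise ModelError("model has no peptide residues to cap")
    first, last = model.peptide_residues[0], model.peptide_residues[-1]
    if model.residue_name(first) == "ACE" and model.residue_name(last) == "NME":
        warnings.warn("peptide already capped; cap_termini is a no-op", stacklevel=2)
        return model

    chain = model.atoms[model.atoms_of_residue(first)[0]].chain_id
    new_atoms = list(model.atoms)
    pep = list(model.peptide_residues)

    if model.residue_name(first) != "ACE":
        n0 = model.atoms[model.atom_index(first, "N")].position
        ca0 = model.atoms[model.atom_index(first, "CA")].position
        c0 = model.atoms[model.atom_index(first, "C")].position
        c_ace = place_atom(c0, ca0, n0, _AMIDE_C_N, 121.7 * DEG, 180.0 * DEG)
        o_ace = place_atom(ca0, n0, c_ace, _C_O, 122.9 * DEG, 0.0)
        ch3 = place_atom(ca0, n0, c_ace, _C_CH3, 116.6 * DEG, 180.0 * DEG)
        ace = [
            AtomRecord(0, "CH3", "C", first, "ACE", chain, ch3),
            AtomRecord(0, "C", "C", first, "ACE", chain, c_ace),
            AtomRecord(0, "O", "O", first, "ACE", chain, o_ace),
        ]
        insert_at = model.atoms_of_residue(first)[0]
        new_atoms = new_atoms[:insert_at] + ace + new_atoms[insert_at:]
        pep = [first] + pep  # placeholder; renumbering fixes indices below

    model_tmp = ComplexModel(
        atoms=new_atoms,
        peptide_residues=pep,
        scaffold_residues=list(model.scaffold_residues),
    )

    if model.residue_name(last) != "NME":
        nl = model.atoms[model.atom_index(last, "N")].position
        cal = model.atoms[model.atom_index(last, "CA")].position
        cl = model.atoms[model.atom_index(last, "C")].position
        ol = model.atoms[model.atom_index(last, "O")].position
        d_o = dihedral_angle(nl, cal, cl, ol)
        n_nme = place_atom(nl, cal, cl, _AMIDE_C_N, 116.6 * DEG, d_o + np.pi)
        ch3 = place_atom(cal, cl, n_nme, _N_CH3, 121.7 * DEG, 180.0 * DEG)
        nme = [
            AtomRecord(0, "N", "N", last, "NME", chain, n_nme),
            AtomRecord(0, "CH3", "C", last, "NME", chain, ch3),
        ]
        insert_at = model_tmp.atoms_of_residue(last)[-1] + 1
        new_atoms = model_tmp.atoms[:insert_at] + nme + model_tmp.atoms[insert_at:]
    else:
        new_atoms = model_tmp.atoms

    return _renumber(new_atoms, model, capped=True)


def _renumber(atoms: list[AtomRecord], old_model: ComplexModel, capped: bool) -> ComplexModel:
    """Assign sequential residue indices/serials after insertion of caps."""
    peptide_chain_ids = {
        old_model.atoms[old_model.atoms_of_residue(ri)[0]].chain_id
        for ri in old_model.peptide_residues
    }
    new_index = 0
    prev_key = None
    peptide, scaffold = [], []
    out: list[AtomRecord] = []
    for a in atoms:
        key = (a.chain_id, a.residue_index, a.residue_name)
        if key != prev_key:
            new_index += 1
            prev_key = key
            if a.chain_id in peptide_chain_ids:
                peptide.append(new_index)
            else:
                scaffold.append(new_index)
        out.append(
            AtomRecord(
                serial=len(out) + 1,
                name=a.name,
                element=a.element,
                residue_index=new_index,
                residue_name=a.residue_name,
                chain_id=a.chain_id,
                position=a.position.copy(),
                charge=a.charge,
                mass=a.mass,
            )
        )
    return ComplexModel(
        atoms=out,
        peptide_residues=peptide,
        scaffold_residues=scaffold,
        needs_minimization=old_model.needs_minimization or capped,
    )


# ---------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------

def mutate_residue(model: ComplexModel, residue_index: int, new_name: str) -> ComplexModel:
    """Replace the side chain of one residue, keeping its backbone in place.

    Backbone atoms (N, CA, C, O — and CB when both old and new residue
    have one) retain their coordinates; the remaining side-chain atoms
    are grafted from the ideal template superposed on the backbone.  The
    returned model is flagged as requiring minimization.
    """
    new_name = new_name.upper()
    if new_name not in AMINO_ACIDS:
        raise UnknownResidueError(f"cannot mutate to unknown residue '{new_name}'")
    old_name = model.residue_name(residue_index)
    if old_name not in AMINO_ACIDS:
        raise UnsupportedMutationError(f"residue {residue_index} ({old_name}) is not mutable")
    if "PRO" in (old_name, new_name) and old_name != new_name:
        raise UnsupportedMutationError(
            "mutations to/from proline would cross a cis/trans backbone boundary"
        )
    if old_name == new_name:
        return model.copy()

    model = model.copy()
    template = get_template(new_name)
    res_atoms = model.atoms_of_residue(residue_index)
    have = {model.atoms[i].name: i for i in res_atoms}
    keep = [n for n in ("N", "CA", "C", "O") if n in have]
    if {"N", "CA", "C"} - set(keep):
        raise ModelError(f"residue {residue_index} missing backbone atoms for mutation")
    anchors = ["N", "CA", "C"]
    if "CB" in have and "CB" in template.atom_names:
        anchors.append("CB")
        keep.append("CB")

    tmpl_anchor = np.array([template.coords[template.index(n)] for n in anchors])
    model_anchor = np.array([model.atoms[have[n]].position for n in anchors])
    rot, trans, _ = kabsch(tmpl_anchor, model_anchor)
    placed = apply_transform(template.coords, rot, trans)

    first_atom = model.atoms[res_atoms[0]]
    new_res_atoms = []
    for k, name in enumerate(template.atom_names):
        if name in keep:
            pos = model.atoms[have[name]].position.copy()
        else:
            pos = placed[k]
        new_res_atoms.append(
            AtomRecord(
                serial=0,
                name=name,
                element=template.elements[k],
                residue_index=residue_index,
                residue_name=new_name,
                chain_id=first_atom.chain_id,
                position=pos,
            )
        )

    atoms = [a for i, a in enumerate(model.atoms) if i not in set(res_atoms)]
    atoms[res_atoms[0]:res_atoms[0]] = new_res_atoms
    for s, a in enumerate(atoms):
        a.serial = s + 1
    out = ComplexModel(
        atoms=atoms,
        peptide_residues=list(model.peptide_residues),
        scaffold_residues=list(model.scaffold_residues),
        needs_minimization=True,
    )
    return out


# ---------------------------------------------------------------------
# Mobility
# ---------------------------------------------------------------------

def assign_mobility(model: ComplexModel, scheme: str = "bound-peptide") -> ComplexModel:
    """Attach the mobility mask used by the restrained annealing protocol.

    ``"bound-peptide"`` (default): peptide residues C-terminal to the
    phosphotyrosine (including the NME cap) are free; the
    phosphotyrosine and anything N-terminal of it (including the ACE
    cap) are positionally restrained; the scaffold is frozen.
    ``"all-free"``: every atom free (no restraints).
    """
    model = model.copy()
    n = model.n_atoms
    if scheme == "all-free":
        model.mobility = np.full(n, Mobility.FREE, dtype=np.int8)
        model.reference_positions = model.coords
        return model
    if scheme != "bound-peptide":
        raise MobilitySchemeError(f"unknown mobility scheme '{scheme}'")

    ptyr = model.find_ptyr()
    if ptyr is None:
        raise MobilitySchemeError(
            "bound-peptide scheme requires a phosphotyrosine (PTR) residue"
        )
    mobility = np.full(n, Mobility.FROZEN, dtype=np.int8)
    pep = set(model.peptide_residues)
    for i, a in enumerate(model.atoms):
        if a.residue_index in pep:
            mobility[i] = Mobility.FREE if a.residue_index > ptyr else Mobility.RESTRAINED
    model.mobility = mobility
    model.reference_positions = model.coords
    return model
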