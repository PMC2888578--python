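"""Build peptides from internal coordinates (backbone dihedral control).

Used by the synthetic-data generators and by the ideal reference
conformations (extended, alpha-helix, type-I beta-turn).
"""

from __future__ import annotations

import numpy as np

from .geometry import place_atom
from .structure import AtomRecord, ComplexModel
from .templates import get_template

__all__ = [
    "build_backbone",
    "build_peptide",
    "set_phi_psi",
    "EXTENDED",
    "ALPHA_HELIX",
    "TYPE_I_TURN",
]

DEG = np.pi / 180.0

# canonical backbone internal coordinates (Engh-Huber-like)
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.229
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.2, 116.6, 121.7, 120.4

#: named (phi, psi) in degrees
EXTENDED = (-120.0, 120.0)
ALPHA_HELIX = (-57.0, -47.0)
#: type-I turn applies to the two central residues of a 4-residue reversal
TYPE_I_TURN = ((-60.0, -30.0), (-90.0, 0.0))


def build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates for a chain with given (phi, psi) per residue.

    Angles in degrees; omega is fixed trans (180°).  phi of the first
    residue is irrelevant (no preceding carbonyl) but must be supplied.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    out: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_N_CA, 0.0, 0.0])
    ang = _ANG_N_CA_C * DEG
    c = ca + _CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    for i, (phi, psi) in enumerate(phi_psi):
        if i > 0:
            prev = out[-1]
            n = place_atom(prev["N"], prev["CA"], prev["C"],
                           _C_N, _ANG_CA_C_N * DEG, phi_psi[i - 1][1] * DEG)
            ca = place_atom(prev["CA"], prev["C"], n,
                            _N_CA, _ANG_C_N_CA * DEG, 180.0 * DEG)  # omega trans
            c = place_atom(prev["C"], n, ca, _CA_C, _ANG_N_CA_C * DEG, phi * DEG)
        o = place_atom(n, ca, c, _C_O, _ANG_CA_C_O * DEG, (psi + 180.0) * DEG)
        out.append({"N": n, "CA": ca, "C": c, "O": o})
    return out


def build_peptide(
    sequence: list[str],
    phi_psi: list[tuple[float, float]] | tuple[float, float] = EXTENDED,
    chain_id: str = "P",
) -> ComplexModel:
    """Build a peptide model with ideal side chains at given backbone dihedrals.

    Side chains are grafted from the ideal residue templates by
    superposing each template's N/CA/C onto the constructed backbone.
    """
    from .geometry import apply_transform, kabsch

    if isinstance(phi_psi, tuple) and np.isscalar(phi_psi[0]):
        phi_psi = [phi_psi] * len(sequence)
    if len(phi_psi) != len(sequence):
        raise ValueError("phi_psi length must match sequence length")
    backbone = build_backbone(list(phi_psi))

    atoms: list[AtomRecord] = []
    for ri, res_name in enumerate(sequence, start=1):
        res_name = res_name.upper()
        template = get_template(res_name)
        bb = backbone[ri - 1]
        anchors = ["N", "CA", "C"]
        tmpl_anchor = np.array([template.coords[template.index(a)] for a in anchors])
        target = np.array([bb[a] for a in anchors])
        rot, trans, _ = kabsch(tmpl_anchor, target)
        placed = apply_transform(template.coords, rot, trans)
        for k, name in enumerate(template.atom_names):
            pos = bb[name] if name in bb else placed[k]
            atoms.append(
                AtomRecord(
                    serial=len(atoms) + 1,
                    name=name,
                    element=template.elements[k],
                    residue_index=ri,
                    residue_name=res_name,
                    chain_id=chain_id,
                    position=pos,
                )
            )
    return ComplexModel(atoms=atoms, peptide_residues=list(range(1, len(sequence) + 1)))


def _rotate_about_axis(coords, moving, p0, p1, delta):
    """Rodrigues rotation of ``moving`` atom indices about the p0->p1 axis."""
    axis = np.asarray(p1, float) - p0
    axis /= np.linalg.norm(axis)
    x = coords[moving] - p1
    cos_d, sin_d = np.cos(delta), np.sin(delta)
    rotated = (
        x * cos_d
        + np.cross(axis, x) * sin_d
        + np.outer(x @ axis, axis) * (1.0 - cos_d)
    )
    coords[moving] = rotated + p1


def set_phi_psi(model, coords, residue_index: int,
                phi: float | None = None, psi: float | None = None) -> np.ndarray:
    """Drive backbone torsions of one residue, moving everything downstream.

    ``phi``/``psi`` in degrees.  Rotating phi (about N-CA) carries the
    side chain, the carbonyl and all later residues; rotating psi
    (about CA-C) carries the carbonyl oxygen and all later residues.
    Upstream atoms — in particular a restrained anchor residue — stay
    exactly in place.  Returns a modified copy of ``coords``.
    """
    from .geometry import dihedral_angle

    coords = np.array(coords, float)
    residues = model.residue_indices()
    pos_in_chain = residues.index(residue_index)
    prev_res = residues[pos_in_chain - 1] if pos_in_chain > 0 else None

    i_n = model.atom_index(residue_index, "N")
    i_ca = model.atom_index(residue_index, "CA")
    i_c = model.atom_index(residue_index, "C")
    later = [
        k for k, a in enumerate(model.atoms)
        if a.residue_index > residue_index and a.residue_index in model.peptide_residues
    ]

    if phi is not None:
        if prev_res is None:
            raise ValueError("phi undefined for the first residue")
        i_cprev = model.atom_index(prev_res, "C")
        current = dihedral_angle(coords[i_cprev], coords[i_n], coords[i_ca], coords[i_c])
        moving = [
            k for k in model.atoms_of_residue(residue_index)
            if model.atoms[k].name not in ("N", "CA")
        ] + later
        _rotate_about_axis(coords, moving, coords[i_n], coords[i_ca],
                           phi * DEG - current)

    if psi is not None:
        i_o = model.atom_index(residue_index, "O")
        # measure psi against the next backbone nitrogen when present,
        # otherwise against the carbonyl oxygen (psi' = psi + 180)
        next_n = None
        if pos_in_chain + 1 < len(residues):
            try:
                next_n = model.atom_index(residues[pos_in_chain + 1], "N")
            except KeyError:
                next_n = None
        if next_n is not None:
            current = dihedral_angle(coords[i_n], coords[i_ca], coords[i_c], coords[next_n])
        else:
            current = dihedral_angle(coords[i_n], coords[i_ca], coords[i_c], coords[i_o]) - np.pi
        moving = [i_o] + later
        _rotate_about_axis(coords, moving, coords[i_ca], coords[i_c],
                           psi * DEG - current)
    return coords
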