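"""Synthetic inputs: toy complexes, reference poses, noisy titrations.

Everything the pipeline consumes can be generated here without any
external file or network access:

* :func:`make_toy_complex` — a small phosphopeptide (PTR-Glu-Glu-Ile by
  default, ACE/NME-capped) bound to a rigid mock scaffold assembled
  from single-bead pseudo-residues: two cationic anchor sites that form
  salt bridges to the phosphate (the pocket-arginine analogue), an
  apolar pocket of beads engineered around the pTyr+3 side chain of
  the extended pose, and polar shelf beads that stabilize a compact
  (helix-like) conformation.  The landscape has exactly two designed
  basins — "pocket" (extended-like, side chain inserted) and "compact"
  — whose energy gap is set by the pocket well depth.
* :func:`make_reference_set` — ideal extended / helical / type-I-turn
  CA references for a segment.
* :func:`make_titration` — 4-parameter-logistic fluorescence-
  polarization titrations with Gaussian read noise and known true IC50.

All generators are pure functions of their spec plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import ReferenceConformation, build_references, ca_rmsd
from .binding import TitrationSeries, inhibition_percentage
from .forcefield import ForceFieldParameters, load_parameters, neutralize_charges
from .pepbuild import EXTENDED, build_peptide, set_phi_psi
from .structure import (
    AtomRecord,
    ComplexModel,
    SpecificitySegment,
    assign_mobility,
    cap_termini,
    specificity_segment,
)

__all__ = [
    "ToyComplexSpec",
    "ToyComplex",
    "TitrationTruth",
    "make_toy_complex",
    "mutate_toy",
    "designed_basin_energy",
    "make_titration",
    "make_reference_set",
    "COMPACT_PHI_PSI",
    "POCKET_DEPTH_SERIES",
]

#: backbone dihedrals of the designed compact basin: a loose helix-like
#: turn that relaxes without steric strain in the extended-atom model
COMPACT_PHI_PSI = (-60.0, -40.0)

#: desk-scale analogue of the pTyr+3 hydrophobic series: the pocket
#: well depth scales with the buried side-chain size, so glycine — with
#: no side chain to insert — gets a near-zero well (its residual value
#: represents backbone-pocket contact).
POCKET_DEPTH_SERIES = {
    "ILE": 6.0,
    "LEU": 5.2,
    "VAL": 4.0,
    "ALA": 1.5,
    "GLY": 0.5,
}


@dataclass
class ToyComplexSpec:
    """Design parameters of the synthetic peptide–scaffold complex."""

    sequence: tuple[str, ...] = ("PTR", "GLU", "GLU", "ILE")
    pocket_depth: float = 4.0  # kcal/mol, LJ well depth of each pocket bead
    pocket_radius: float = 3.9  # Å, bead distance from the buried side-chain tip
    shelf_charge: float = -0.3  # e, polar shelf beads
    seed: int = 0

    def __post_init__(self):
        if len(self.sequence) < 3:
            raise ValueError("toy peptide needs at least 3 residues")
        if "PTR" not in [s.upper() for s in self.sequence]:
            raise ValueError("toy peptide needs a phosphotyrosine-like anchor")


@dataclass
class ToyComplex:
    """Generated complex plus its documented basin geometry."""

    model: ComplexModel  # capped, neutralized, mobility-assigned; extended start
    params: ForceFieldParameters
    spec: ToyComplexSpec
    extended_coords: np.ndarray  # designed "pocket" basin start (= model coords)
    compact_coords: np.ndarray  # designed "compact" basin start
    pocket_center: np.ndarray
    segment: SpecificitySegment = None

    def segment_ca_indices(self) -> list[int]:
        return [self.model.atom_index(ri, "CA") for ri in self.segment.residue_indices]

    def pocket_engagement(self, coords: np.ndarray) -> float:
        """Lennard-Jones interaction (kcal/mol) between peptide and pocket beads.

        This is the designed reaction coordinate of the toy landscape: a
        conformation with part of the peptide buried in the apolar
        pocket has a strongly negative engagement energy, scaled by the
        pocket depth.
        """
        x = np.asarray(coords, float)
        bead_idx = np.array([
            i for i, a in enumerate(self.model.atoms) if a.residue_name == "SCB"
        ])
        pep_idx = np.array([
            i for i, a in enumerate(self.model.atoms)
            if a.residue_index in self.model.peptide_residues
        ])
        types = self.model.atom_types
        rstar = np.array([self.params.atom_types[types[i]][0] for i in pep_idx])
        eps = np.array([self.params.atom_types[types[i]][1] for i in pep_idx])
        rstar_b, eps_b = self.params.atom_types["XB"]
        total = 0.0
        for b in bead_idx:
            d = np.linalg.norm(x[pep_idx] - x[b], axis=1)
            s6 = ((rstar + rstar_b) / d) ** 6
            total += float(np.sum(np.sqrt(eps * eps_b) * (s6**2 - 2.0 * s6)))
        return total

    def label_basin(self, coords: np.ndarray, threshold: float = -1.0) -> str:
        """Basin label by pocket engagement: "pocket" when the peptide is
        bound in the apolar hole (engagement below ``threshold`` kcal/mol),
        else "compact"."""
        return "pocket" if self.pocket_engagement(coords) < threshold else "compact"


def _bead(name: str, res_name: str, residue_index: int, position) -> AtomRecord:
    element = {"SCB": "C", "SCP": "N", "SCN": "O"}[res_name]
    return AtomRecord(
        serial=0, name=name, element=element, residue_index=residue_index,
        residue_name=res_name, chain_id="S", position=np.asarray(position, float),
    )


def make_toy_complex(spec: ToyComplexSpec | None = None) -> ToyComplex:
    """Build the two-basin toy complex (deterministic under its seed).

    Basin locations (documented contract): the *pocket* basin is the
    extended-conformation start with the C-terminal hydrophobic side
    chain inserted between the pocket beads; the *compact* basin is the
    helix-like start stabilized by the polar shelf beads.  Setting
    ``pocket_depth`` to 0 removes the pocket interaction entirely (the
    beads become ghosts): the pocket basin then loses its energetic
    advantage and the designed global minimum becomes the compact basin
    (probe with :func:`designed_basin_energy`).
    """
    spec = spec or ToyComplexSpec()
    sequence = [s.upper() for s in spec.sequence]

    extended = cap_termini(build_peptide(sequence, EXTENDED))
    ptyr = next(ri for ri in extended.residue_indices()
                if extended.residue_name(ri) == "PTR")
    # compact (helix-like) start: drive the free segment's phi/psi to
    # helical values; the restrained anchor (ACE + PTR) stays in place
    free_residues = [
        ri for ri in extended.peptide_residues
        if ri > ptyr and extended.residue_name(ri) != "NME"
    ]
    compact_coords_pep = extended.coords
    for ri in free_residues:
        compact_coords_pep = set_phi_psi(
            extended, compact_coords_pep, ri,
            phi=COMPACT_PHI_PSI[0], psi=COMPACT_PHI_PSI[1],
        )

    # --- scaffold ----------------------------------------------------
    beads: list[AtomRecord] = []
    next_res = extended.residue_indices()[-1] + 1

    # cationic anchor sites off the phosphate oxygens
    p_pos = extended.atoms[extended.atom_index(ptyr, "P")].position
    for o_name in ("O1P", "O2P"):
        o_pos = extended.atoms[extended.atom_index(ptyr, o_name)].position
        direction = (o_pos - p_pos) / np.linalg.norm(o_pos - p_pos)
        beads.append(_bead("N1", "SCP", next_res, o_pos + 2.9 * direction))
        next_res += 1

    # apolar pocket around the buried side chain of the last residue
    last = max(ri for ri in extended.peptide_residues
               if extended.residue_name(ri) not in ("ACE", "NME"))
    tip_name = _buried_tip(extended, last)
    tip = extended.atoms[extended.atom_index(last, tip_name)].position
    ca_last = extended.atoms[extended.atom_index(last, "CA")].position
    axis = tip - ca_last
    axis /= np.linalg.norm(axis)
    perp1 = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp1) < 1e-6:
        perp1 = np.cross(axis, [0.0, 1.0, 0.0])
    perp1 /= np.linalg.norm(perp1)
    perp2 = np.cross(axis, perp1)
    r0 = spec.pocket_radius
    pocket_positions = [tip + r0 * axis]
    for angle in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
        direction = 0.574 * axis + 0.819 * (np.cos(angle) * perp1 + np.sin(angle) * perp2)
        pocket_positions.append(tip + r0 * direction)
    for pos in pocket_positions:
        beads.append(_bead("C1", "SCB", next_res, pos))
        next_res += 1
    pocket_center = np.mean(pocket_positions, axis=0)

    # polar shelf beads near the compact pose of the peptide C-terminus
    nme_res = extended.residue_indices()[-1]
    shelf_targets = [
        compact_coords_pep[extended.atom_index(nme_res, "CH3")],
        compact_coords_pep[extended.atom_index(last, "C")],
    ]
    shelf_center = np.mean(shelf_targets, axis=0)
    away = shelf_center - np.mean(compact_coords_pep, axis=0)
    away /= np.linalg.norm(away)
    for k, tgt_pos in enumerate(shelf_targets):
        beads.append(_bead("O1", "SCN", next_res, tgt_pos + 3.3 * away))
        next_res += 1

    atoms = [a for a in extended.atoms] + beads
    for s, a in enumerate(atoms):
        a.serial = s + 1
    model = ComplexModel(
        atoms=atoms,
        peptide_residues=list(extended.peptide_residues),
        scaffold_residues=[a.residue_index for a in beads],
    )

    params = load_parameters().with_type_eps("XB", spec.pocket_depth)
    if abs(spec.shelf_charge + 0.5) > 1e-12:
        params = _with_shelf_charge(params, spec.shelf_charge)
    model = assign_mobility(model, "bound-peptide")
    model = neutralize_charges(model, params)
    model.validate()

    n_pep = len(extended.atoms)
    compact_full = model.coords.copy()
    compact_full[:n_pep] = compact_coords_pep

    return ToyComplex(
        model=model,
        params=params,
        spec=spec,
        extended_coords=model.coords,
        compact_coords=compact_full,
        pocket_center=pocket_center,
        segment=specificity_segment(model),
    )


def _buried_tip(model: ComplexModel, residue_index: int) -> str:
    """Outermost side-chain heavy atom of the pocket-inserted residue."""
    for name in ("CD1", "CG1", "CG", "CB", "CA"):
        try:
            model.atom_index(residue_index, name)
            return name
        except KeyError:
            continue
    return "CA"


def _with_shelf_charge(params: ForceFieldParameters, charge: float) -> ForceFieldParameters:
    residues = {k: dict(v) for k, v in params.residues.items()}
    t, _ = residues[("SCN", "standard")]["O1"]
    residues[("SCN", "standard")]["O1"] = (t, float(charge))
    return ForceFieldParameters(
        params.atom_types, params.bonds, params.angles, params.dihedrals,
        residues, dict(params.options),
    )


# ---------------------------------------------------------------------
# Reference conformations
# ---------------------------------------------------------------------

def make_reference_set(n_residues: int) -> list[ReferenceConformation]:
    """Ideal extended / helical / beta-turn references for a segment."""
    return build_references(n_residues)


# ---------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------

@dataclass
class TitrationTruth:
    """Ground truth for a synthetic competition titration."""

    ic50: float = 2.0e-6  # M
    hill: float = 1.0
    fp0: float = 200.0  # mP, blank control (domain + probe)
    fpb: float = 60.0  # mP, background control
    noise_sd: float = 0.0  # mP, Gaussian read noise
    concentrations: np.ndarray = field(
        default_factory=lambda: np.concatenate(
            [[0.0], np.geomspace(1e-8, 1e-4, 11)]  # 0-100 µM, the assayed range
        )
    )
    seed: int = 0

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, float)
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    def grid_spans_ic50(self) -> bool:
        nz = self.concentrations[self.concentrations > 0]
        return bool(len(nz)) and nz.min() <= self.ic50 <= nz.max()


def make_titration(truth: TitrationTruth, peptide: str = "synthetic") -> TitrationSeries:
    """Noisy FP titration whose noise-free fit recovers the true IC50 exactly.

    The true inhibition follows a 4PL running 0 → 100%; FP readings are
    back-computed through the inhibition-percentage equation and Gaussian
    noise is added on the FP (instrument) scale.
    """
    if not truth.grid_spans_ic50():
        import warnings

        warnings.warn("concentration grid does not span the true IC50; "
                      "the fitted IC50 will be an extrapolation", stacklevel=2)
    rng = np.random.default_rng(truth.seed)
    c = truth.concentrations
    with np.errstate(divide="ignore"):
        ip = np.where(
            c > 0, 100.0 / (1.0 + (truth.ic50 / np.where(c > 0, c, 1.0)) ** truth.hill), 0.0
        )
    fp = truth.fp0 - ip / 100.0 * (truth.fp0 - truth.fpb)
    fp = fp + rng.normal(scale=truth.noise_sd, size=fp.shape)
    series = TitrationSeries(
        peptide=peptide, concentrations=c, fp_readings=fp,
        fp0=truth.fp0, fpb=truth.fpb,
    )
    # round-trip consistency of the IP equation on noise-free data
    if truth.noise_sd == 0:
        assert np.allclose(inhibition_percentage(fp, truth.fp0, truth.fpb), ip)
    return series


def mutate_toy(toy: ToyComplex, new_resname: str) -> ToyComplex:
    """Replace the pocket-inserted (pTyr+3) residue, keeping the scaffold.

    Mirrors how mutant complexes are built from a template crystal
    structure: the scaffold (and hence the pocket sculpted around the
    original side chain) is untouched, the side chain is swapped and the
    model is flagged for re-minimization.  Basin-start coordinates are
    rebuilt consistently for the new atom count.
    """
    from .structure import mutate_residue

    last = toy.segment.residue_indices[-1]

    def _mutant_coords(coords):
        m = toy.model.copy()
        m.set_coords(coords)
        return mutate_residue(m, last, new_resname)

    mutant_ext = _mutant_coords(toy.extended_coords)
    mutant_cmp = _mutant_coords(toy.compact_coords)
    model = neutralize_charges(
        assign_mobility(mutant_ext, "bound-peptide"), toy.params
    )
    model.validate()
    return ToyComplex(
        model=model,
        params=toy.params,
        spec=toy.spec,
        extended_coords=model.coords,
        compact_coords=mutant_cmp.coords,
        pocket_center=toy.pocket_center,
        segment=toy.segment,
    )


def designed_basin_energy(
    toy: ToyComplex, which: str, n_quench: int = 5
) -> tuple[float, np.ndarray]:
    """Relaxed floor energy of one designed basin ("pocket" or "compact").

    A single minimization path on a rugged landscape is a noisy probe,
    so the basin floor is estimated as the best of ``n_quench``
    seeded low-temperature quenches: tethered minimization toward the
    designed start, a short 150 K run, then a free staged minimization.
    Only quenches that stay in the designed basin count.  Returns
    ``(energy, coordinates)`` of the best quench.
    """
    from .dynamics import (
        PRE_SA_MINIMIZATION,
        MDState,
        MinimizationSpec,
        minimize_positions,
        run_md,
    )
    from .forcefield import EnergySystem, RestraintSet

    start = {"pocket": toy.extended_coords, "compact": toy.compact_coords}[which]
    mobile_idx = np.array(
        [i for i, a in enumerate(toy.model.atoms)
         if a.residue_index not in toy.model.scaffold_residues]
    )
    tether = RestraintSet(mobile_idx, start[mobile_idx], k=5.0)
    tethered = EnergySystem(toy.model, toy.params, restraints=tether)
    x1, _ = minimize_positions(tethered, start, MinimizationSpec(100, 300))
    free = EnergySystem(toy.model, toy.params)

    best: tuple[float, np.ndarray] | None = None
    for seed in range(n_quench):
        if seed == 0:
            x_start = x1
        else:
            state = MDState(x1.copy(), np.zeros_like(x1), free.masses, free.frozen,
                            seed=seed)
            state, _ = run_md(state, free, 150.0, duration=0.2, dt=0.001,
                              rng=np.random.default_rng(seed))
            x_start = state.positions
        x2, _ = minimize_positions(free, x_start, PRE_SA_MINIMIZATION)
        e2 = free.energy(x2)["total"]
        if toy.label_basin(x2) != which:
            continue
        if best is None or e2 < best[0]:
            best = (e2, x2)
    if best is None:  # every quench left the designed basin
        x2, _ = minimize_positions(free, x1, PRE_SA_MINIMIZATION)
        best = (free.energy(x2)["total"], x2)
    return best
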