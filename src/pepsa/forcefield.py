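"""Implicit-solvent molecular-mechanics energy model.

The potential is a classical bonded + nonbonded form evaluated on heavy
atoms:

* harmonic bonds and angles, ``E = k (x - x0)^2`` (AMBER convention:
  the force constant already contains the factor 1/2);
* Fourier dihedral terms ``E = (V_n/2) (1 + cos(n phi - gamma))``;
* 12-6 Lennard-Jones with Lorentz-Berthelot combination on ``r*`` and a
  geometric mean on well depths;
* Coulomb electrostatics under a distance-dependent dielectric
  ``eps = R_ij``, so a charge pair contributes
  ``332.0636 q_i q_j / R_ij^2`` kcal/mol;
* hard atom-based truncation of the nonbonded sum at 12 Å;
* exclusion of 1-2 and 1-3 pairs, with 1-4 electrostatics divided by
  1.2 and 1-4 van der Waals by 2.0;
* harmonic positional restraints ``E = k |r - r_anchor|^2``
  (note: not ``k/2`` — the same convention as the bond term);
* pairs (and bonded terms) internal to the frozen scaffold are skipped
  by default: they are a constant offset for restrained sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._kernels import HAVE_NUMBA, energy_forces_kernel
from .structure import ComplexModel, Mobility
from .templates import get_template

__all__ = [
    "ForceFieldParameters",
    "EnergyModel",
    "RestraintSet",
    "EnergySystem",
    "load_parameters",
    "assign_charges",
    "neutralize_charges",
    "total_energy",
    "forces",
    "ParameterizationError",
]

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)
DEFAULT_RESTRAINT_K = 25.0  # kcal/(mol·Å²)


class ParameterizationError(ValueError):
    pass


@dataclass
class ForceFieldParameters:
    """Parsed contents of a parameter file (see data/minimal.ff)."""

    atom_types: dict[str, tuple[float, float]]  # type -> (rstar, eps)
    bonds: dict[tuple[str, str], tuple[float, float]]  # (t1,t2) sorted -> (k, r0)
    angles: dict[tuple[str, str, str], tuple[float, float]]  # theta0 in rad
    dihedrals: dict[tuple[str, str], list[tuple[float, int, float]]]  # central pair -> terms
    residues: dict[tuple[str, str], dict[str, tuple[str, float]]]  # (res, form) -> atom -> (type, q)
    options: dict[str, float | str] = field(default_factory=dict)

    def residue_forms(self, res_name: str) -> list[str]:
        return [form for (name, form) in self.residues if name == res_name]

    def with_type_eps(self, type_name: str, eps: float) -> "ForceFieldParameters":
        """Copy with one LJ well depth replaced (used to tune the toy pocket)."""
        atom_types = dict(self.atom_types)
        if type_name not in atom_types:
            raise ParameterizationError(f"unknown atom type '{type_name}'")
        rstar, _ = atom_types[type_name]
        atom_types[type_name] = (rstar, float(eps))
        return ForceFieldParameters(
            atom_types, self.bonds, self.angles, self.dihedrals, self.residues, dict(self.options)
        )


@dataclass
class EnergyModel:
    """Nonbonded treatment: cutoff, dielectric mode, scalings, exclusions."""

    cutoff: float = 12.0  # Å
    coulomb_constant: float = COULOMB_CONSTANT
    scale_ee_14: float = 1.2  # divisor for 1-4 electrostatics
    scale_vdw_14: float = 2.0  # divisor for 1-4 van der Waals
    include_frozen_pairs: bool = False

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class RestraintSet:
    atom_indices: np.ndarray
    anchors: np.ndarray
    k: float = DEFAULT_RESTRAINT_K

    def __post_init__(self):
        self.atom_indices = np.asarray(self.atom_indices, dtype=int)
        self.anchors = np.asarray(self.anchors, dtype=float)
        if self.k < 0:
            raise ValueError("restraint constant must be non-negative")

    @classmethod
    def from_model(cls, model: ComplexModel, k: float = DEFAULT_RESTRAINT_K) -> "RestraintSet":
        if model.mobility is None:
            return cls(np.empty(0, dtype=int), np.empty((0, 3)), k)
        idx = np.where(np.asarray(model.mobility) == Mobility.RESTRAINED)[0]
        anchors = (
            model.reference_positions[idx]
            if model.reference_positions is not None
            else model.coords[idx]
        )
        return cls(idx, anchors, k)


# ---------------------------------------------------------------------
# Parameter file parsing
# ---------------------------------------------------------------------

def load_parameters(path=None) -> ForceFieldParameters:
    """Load a parameter file; defaults to the packaged minimal set."""
    if path is None:
        from importlib.resources import files

        text = (files("pepsa") / "data" / "minimal.ff").read_text()
        source = "minimal.ff"
    else:
        text = Path(path).read_text()
        source = str(path)

    atom_types: dict = {}
    bonds: dict = {}
    angles: dict = {}
    dihedrals: dict = {}
    residues: dict = {}
    options: dict = {}
    section = None
    res_key = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            header = line.strip("[]").split()
            section = header[0].lower()
            if section == "residue":
                name = header[1].upper()
                form = "standard"
                for tok in header[2:]:
                    if tok.startswith("form="):
                        form = tok.split("=", 1)[1]
                res_key = (name, form)
                residues[res_key] = {}
            continue
        try:
            if section == "options":
                key, value = (t.strip() for t in line.split("=", 1))
                try:
                    options[key] = float(value)
                except ValueError:
                    options[key] = value
            elif section == "atomtypes":
                t, rstar, eps = line.split()
                atom_types[t] = (float(rstar), float(eps))
            elif section == "bonds":
                t1, t2, k, r0 = line.split()
                bonds[tuple(sorted((t1, t2)))] = (float(k), float(r0))
            elif section == "angles":
                t1, t2, t3, k, theta0 = line.split()
                angles[(t1, t2, t3)] = (float(k), np.deg2rad(float(theta0)))
            elif section == "dihedrals":
                t1, t2, t3, t4, v2, n, gamma = line.split()
                key = tuple(sorted((t2, t3)))
                dihedrals.setdefault(key, []).append(
                    (float(v2), int(n), np.deg2rad(float(gamma)))
                )
            elif section == "residue":
                name, t, q = line.split()
                residues[res_key][name] = (t, float(q))
            else:
                raise ValueError("content outside any section")
        except ValueError as exc:
            raise ParameterizationError(f"{source}, line {lineno}: {exc}") from None

    return ForceFieldParameters(atom_types, bonds, angles, dihedrals, residues, options)


# ---------------------------------------------------------------------
# Charge assignment / neutralization
# ---------------------------------------------------------------------

_TITRATABLE = ("ASP", "GLU", "LYS", "ARG")


def _apply_forms(
    model: ComplexModel, params: ForceFieldParameters, forms: dict[int, str]
) -> ComplexModel:
    model = model.copy()
    atom_types: list[str] = []
    for a in model.atoms:
        form = forms.get(a.residue_index, "standard")
        key = (a.residue_name, form)
        if key not in params.residues:
            raise ParameterizationError(
                f"no residue template for {a.residue_name} (form '{form}')"
            )
        table = params.residues[key]
        if a.name not in table:
            raise ParameterizationError(
                f"atom {a.name} of residue {a.residue_index} ({a.residue_name}) "
                "has no charge/type entry"
            )
        t, q = table[a.name]
        a.charge = q
        atom_types.append(t)
    model.atom_types = atom_types
    return model


def assign_charges(
    model: ComplexModel,
    params: ForceFieldParameters,
    forms: dict[int, str] | None = None,
) -> ComplexModel:
    """Assign atom types and full (standard-form) partial charges."""
    return _apply_forms(model, params, forms or {})


def neutralize_charges(
    model: ComplexModel,
    params: ForceFieldParameters,
    keep_charged: tuple[int, ...] = (),
    ptr_form: str = "standard",
) -> ComplexModel:
    """Neutralize titratable residues for the distance-dependent dielectric.

    Asp/Glu switch to their protonated templates and Lys/Arg to neutral
    templates, *except* residues listed in ``keep_charged`` (the two
    phosphate-binding pocket arginines) which retain their full charge.
    The phosphotyrosine always keeps its charged phosphate
    (``ptr_form`` selects di- vs mono-anionic).
    """
    present = {ri for a in model.atoms for ri in (a.residue_index,)}
    missing = set(keep_charged) - present
    if missing:
        raise ParameterizationError(
            f"keep_charged residues not found in model: {sorted(missing)}"
        )
    forms: dict[int, str] = {}
    for ri in sorted(present):
        name = model.residue_name(ri)
        if name in _TITRATABLE and ri not in keep_charged:
            forms[ri] = "neutral"
        elif name == "PTR" and ptr_form != "standard":
            forms[ri] = ptr_form
    return _apply_forms(model, params, forms)


# ---------------------------------------------------------------------
# Topology + compiled energy evaluator
# ---------------------------------------------------------------------

def _build_bonds(model: ComplexModel) -> list[tuple[int, int]]:
    """Intra-residue bonds from templates plus inter-residue amide links."""
    bonds: list[tuple[int, int]] = []
    for ri in model.residue_indices():
        idx = model.atoms_of_residue(ri)
        names = {model.atoms[i].name: i for i in idx}
        template = get_template(model.atoms[idx[0]].residue_name)
        for a, b in template.bonds:
            if a in names and b in names:
                bonds.append((names[a], names[b]))
    # peptide bonds: C(i) - N(i+1), same chain, plausible bond length
    residues = model.residue_indices()
    for ri, rj in zip(residues, residues[1:]):
        try:
            ci = model.atom_index(ri, "C")
            nj = model.atom_index(rj, "N")
        except KeyError:
            continue
        if model.atoms[ci].chain_id != model.atoms[nj].chain_id:
            continue
        dist = np.linalg.norm(model.atoms[ci].position - model.atoms[nj].position)
        if dist < 2.0:
            bonds.append((ci, nj))
    return bonds




def _acc(f: np.ndarray, idx: np.ndarray, contrib: np.ndarray) -> None:
    """Scatter-add per-term force contributions (bincount is faster than add.at)."""
    n = f.shape[0]
    for d in range(3):
        f[:, d] += np.bincount(idx, weights=contrib[:, d], minlength=n)

class EnergySystem:
    """Compiled evaluator of the potential energy and its gradient.

    Compilation (topology perception, parameter lookup, pair-list
    construction) happens once; :meth:`energy` and :meth:`forces` then
    take bare ``(N, 3)`` coordinate arrays, which is what the
    minimizers and the integrator iterate on.
    """

    def __init__(
        self,
        model: ComplexModel,
        params: ForceFieldParameters,
        restraints: RestraintSet | None = None,
        energy_model: EnergyModel | None = None,
        backend: str = "numba",
    ):
        self.model_ref = model
        self.backend = backend if HAVE_NUMBA else "numpy"
        em = energy_model or EnergyModel()
        self.em = em
        if getattr(model, "atom_types", None) is None:
            model = assign_charges(model, params)
        self.charges = model.charges
        self.masses = model.masses
        types = model.atom_types
        unknown = sorted({t for t in types if t not in params.atom_types})
        if unknown:
            raise ParameterizationError(f"atom types without LJ parameters: {unknown}")

        n = model.n_atoms
        self.n_atoms = n
        if model.mobility is None:
            self.frozen = np.zeros(n, dtype=bool)
        else:
            self.frozen = np.asarray(model.mobility) == Mobility.FROZEN
        self.mobile = ~self.frozen

        self.restraints = (
            restraints if restraints is not None else RestraintSet.from_model(model)
        )

        bonds = _build_bonds(model)
        adjacency: dict[int, set[int]] = {i: set() for i in range(n)}
        for i, j in bonds:
            adjacency[i].add(j)
            adjacency[j].add(i)

        def _skip(*atoms) -> bool:
            return (not em.include_frozen_pairs) and all(self.frozen[list(atoms)])

        # bonds
        b_i, b_j, b_k, b_r0 = [], [], [], []
        for i, j in bonds:
            if _skip(i, j):
                continue
            key = tuple(sorted((types[i], types[j])))
            if key not in params.bonds:
                raise ParameterizationError(f"missing bond parameters for types {key}")
            k, r0 = params.bonds[key]
            b_i.append(i), b_j.append(j), b_k.append(k), b_r0.append(r0)
        self.bond_idx = (np.array(b_i, int), np.array(b_j, int))
        self.bond_k = np.array(b_k)
        self.bond_r0 = np.array(b_r0)

        # angles
        a_idx, a_k, a_t0 = [], [], []
        for j in range(n):
            nbrs = sorted(adjacency[j])
            for u in range(len(nbrs)):
                for v in range(u + 1, len(nbrs)):
                    i, k = nbrs[u], nbrs[v]
                    if _skip(i, j, k):
                        continue
                    ti, tj, tk = types[i], types[j], types[k]
                    par = (
                        params.angles.get((ti, tj, tk))
                        or params.angles.get((tk, tj, ti))
                        or params.angles.get(("X", tj, "X"))
                    )
                    if par is None:
                        raise ParameterizationError(
                            f"missing angle parameters for types {(ti, tj, tk)}"
                        )
                    a_idx.append((i, j, k)), a_k.append(par[0]), a_t0.append(par[1])
        self.angle_idx = np.array(a_idx, int).reshape(-1, 3)
        self.angle_k = np.array(a_k)
        self.angle_t0 = np.array(a_t0)

        # proper dihedrals, possibly several Fourier terms per quad
        d_idx, d_v2, d_n, d_g = [], [], [], []
        for j, k in bonds:
            for i in adjacency[j]:
                if i == k:
                    continue
                for l in adjacency[k]:
                    if l == j or l == i:
                        continue
                    if _skip(i, j, k, l):
                        continue
                    key = tuple(sorted((types[j], types[k])))
                    terms = params.dihedrals.get(key)
                    if terms is None:
                        raise ParameterizationError(
                            f"missing dihedral parameters for central types {key}"
                        )
                    for v2, nper, gamma in terms:
                        if v2 == 0.0:
                            continue
                        d_idx.append((i, j, k, l))
                        d_v2.append(v2), d_n.append(nper), d_g.append(gamma)
        self.dihedral_idx = np.array(d_idx, int).reshape(-1, 4)
        self.dihedral_v2 = np.array(d_v2)
        self.dihedral_n = np.array(d_n)
        self.dihedral_g = np.array(d_g)

        # exclusions: 1-2, 1-3 excluded; 1-4 scaled
        pairs12 = {tuple(sorted(b)) for b in bonds}
        pairs13 = set()
        for j in range(n):
            nbrs = sorted(adjacency[j])
            for u in range(len(nbrs)):
                for v in range(u + 1, len(nbrs)):
                    pairs13.add(tuple(sorted((nbrs[u], nbrs[v]))))
        pairs14 = set()
        for j, k in bonds:
            for i in adjacency[j]:
                if i == k:
                    continue
                for l in adjacency[k]:
                    if l in (j, i):
                        continue
                    pairs14.add(tuple(sorted((i, l))))
        pairs13 -= pairs12
        pairs14 -= pairs12 | pairs13

        rstar = np.array([params.atom_types[t][0] for t in types])
        eps = np.array([params.atom_types[t][1] for t in types])

        def _pair_arrays(pair_list):
            if not pair_list:
                empty = np.empty(0)
                return (np.empty(0, int), np.empty(0, int), empty, empty, empty)
            pi = np.array([p[0] for p in pair_list], int)
            pj = np.array([p[1] for p in pair_list], int)
            qq = self.charges[pi] * self.charges[pj] * em.coulomb_constant
            rs = rstar[pi] + rstar[pj]
            ep = np.sqrt(eps[pi] * eps[pj])
            return pi, pj, qq, rs, ep

        excluded = pairs12 | pairs13 | pairs14
        nb_pairs = []
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excluded or _skip(i, j):
                    continue
                nb_pairs.append((i, j))
        self.nb = _pair_arrays(nb_pairs)
        self.nb14 = _pair_arrays(sorted(p for p in pairs14 if not _skip(*p)))

        # contiguous packing for the compiled kernel
        ai, aj, ak = (
            (self.angle_idx[:, 0], self.angle_idx[:, 1], self.angle_idx[:, 2])
            if len(self.angle_idx)
            else (np.empty(0, int),) * 3
        )
        di, dj, dk, dl = (
            (self.dihedral_idx[:, 0], self.dihedral_idx[:, 1],
             self.dihedral_idx[:, 2], self.dihedral_idx[:, 3])
            if len(self.dihedral_idx)
            else (np.empty(0, int),) * 4
        )
        self._packed = tuple(
            np.ascontiguousarray(a)
            for a in (
                self.bond_idx[0], self.bond_idx[1], self.bond_k, self.bond_r0,
                ai, aj, ak, self.angle_k, self.angle_t0,
                di, dj, dk, dl, self.dihedral_v2,
                self.dihedral_n.astype(float), self.dihedral_g,
                *self.nb, *self.nb14,
            )
        )

    # -- evaluation ---------------------------------------------------

    def energy(self, positions: np.ndarray | None = None) -> dict[str, float]:
        """Energy breakdown (kcal/mol): bond, angle, dihedral, lj, coulomb, restraint, total."""
        e, _ = self._evaluate(positions, want_forces=False)
        return e

    def forces(self, positions: np.ndarray | None = None) -> np.ndarray:
        """Analytic forces, kcal/(mol·Å); zero on frozen atoms."""
        _, f = self._evaluate(positions, want_forces=True)
        return f

    def energy_forces(self, positions: np.ndarray | None = None):
        return self._evaluate(positions, want_forces=True)

    def _evaluate(self, positions, want_forces):
        x = self.model_ref.coords if positions is None else np.asarray(positions, float)
        if self.backend == "numba":
            return self._evaluate_numba(x, want_forces)
        f = np.zeros_like(x) if want_forces else None
        e = {}

        # bonds
        bi, bj = self.bond_idx
        if len(bi):
            d = x[bi] - x[bj]
            r = np.linalg.norm(d, axis=1)
            dr = r - self.bond_r0
            e["bond"] = float(np.sum(self.bond_k * dr**2))
            if want_forces:
                fmag = (-2.0 * self.bond_k * dr / r)[:, None] * d
                _acc(f, bi, fmag)
                _acc(f, bj, -fmag)
        else:
            e["bond"] = 0.0

        # angles
        if len(self.angle_idx):
            ai, aj, ak = self.angle_idx.T
            u = x[ai] - x[aj]
            v = x[ak] - x[aj]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cos_t = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1.0, 1.0)
            theta = np.arccos(cos_t)
            dt = theta - self.angle_t0
            e["angle"] = float(np.sum(self.angle_k * dt**2))
            if want_forces:
                sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
                dEdt = 2.0 * self.angle_k * dt
                # grad of theta wrt i and k
                gi = (cos_t[:, None] * u / nu[:, None] ** 2 - v / (nu * nv)[:, None]) / sin_t[:, None]
                gk = (cos_t[:, None] * v / nv[:, None] ** 2 - u / (nu * nv)[:, None]) / sin_t[:, None]
                _acc(f, ai, -dEdt[:, None] * gi)
                _acc(f, ak, -dEdt[:, None] * gk)
                _acc(f, aj, dEdt[:, None] * (gi + gk))
        else:
            e["angle"] = 0.0

        # dihedrals
        if len(self.dihedral_idx):
            di, dj, dk, dl = self.dihedral_idx.T
            b1 = x[dj] - x[di]
            b2 = x[dk] - x[dj]
            b3 = x[dl] - x[dk]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=1)
            m1 = np.cross(n1, b2 / nb2[:, None])
            cos_p = np.sum(n1 * n2, axis=1)
            sin_p = np.sum(m1 * n2, axis=1)
            phi = np.arctan2(sin_p, cos_p)
            arg = self.dihedral_n * phi - self.dihedral_g
            e["dihedral"] = float(np.sum(self.dihedral_v2 * (1.0 + np.cos(arg))))
            if want_forces:
                dEdphi = -self.dihedral_v2 * self.dihedral_n * np.sin(arg)
                sq1 = np.sum(n1 * n1, axis=1)
                sq2 = np.sum(n2 * n2, axis=1)
                gi = (nb2 / sq1)[:, None] * n1
                gl = -(nb2 / sq2)[:, None] * n2
                c12 = (np.sum(b1 * b2, axis=1) / nb2**2)[:, None]
                c32 = (np.sum(b3 * b2, axis=1) / nb2**2)[:, None]
                gj = -(1.0 + c12) * gi + c32 * gl
                gk = c12 * gi - (1.0 + c32) * gl
                _acc(f, di, -dEdphi[:, None] * gi)
                _acc(f, dj, -dEdphi[:, None] * gj)
                _acc(f, dk, -dEdphi[:, None] * gk)
                _acc(f, dl, -dEdphi[:, None] * gl)
        else:
            e["dihedral"] = 0.0

        # nonbonded
        e_lj = e_coul = 0.0
        for (pi, pj, qq, rs, ep), (s_ee, s_vdw), use_cutoff in (
            (self.nb, (1.0, 1.0), True),
            (self.nb14, (self.em.scale_ee_14, self.em.scale_vdw_14), False),
        ):
            if not len(pi):
                continue
            d = x[pi] - x[pj]
            r2 = np.sum(d * d, axis=1)
            if use_cutoff:
                mask = r2 <= self.em.cutoff**2
                if not mask.all():
                    pi, pj, qq, rs, ep = pi[mask], pj[mask], qq[mask], rs[mask], ep[mask]
                    d, r2 = d[mask], r2[mask]
                if not len(pi):
                    continue
            inv_r2 = 1.0 / r2
            s6 = (rs**2 * inv_r2) ** 3
            lj = ep * (s6**2 - 2.0 * s6) / s_vdw
            coul = qq * inv_r2 / s_ee
            e_lj += float(np.sum(lj))
            e_coul += float(np.sum(coul))
            if want_forces:
                # dE/dr * 1/r, assembled per pair
                dlj = ep * (-12.0 * s6**2 + 12.0 * s6) * inv_r2 / s_vdw
                dcoul = -2.0 * coul * inv_r2
                fmag = -(dlj + dcoul)[:, None] * d
                _acc(f, pi, fmag)
                _acc(f, pj, -fmag)
        e["lj"] = e_lj
        e["coulomb"] = e_coul

        # restraints
        rset = self.restraints
        if len(rset.atom_indices):
            disp = x[rset.atom_indices] - rset.anchors
            e["restraint"] = float(rset.k * np.sum(disp**2))
            if want_forces:
                _acc(f, rset.atom_indices, -2.0 * rset.k * disp)
        else:
            e["restraint"] = 0.0

        e["total"] = sum(e.values())
        if want_forces:
            f[self.frozen] = 0.0
        return e, f




def _evaluate_numba(self, x, want_forces):
    f = np.zeros_like(x)
    rset = self.restraints
    terms = energy_forces_kernel(
        np.ascontiguousarray(x), f, *self._packed,
        1.0 / self.em.scale_ee_14, 1.0 / self.em.scale_vdw_14,
        self.em.cutoff**2,
        np.ascontiguousarray(rset.atom_indices),
        np.ascontiguousarray(rset.anchors.reshape(-1, 3)),
        float(rset.k),
    )
    e = dict(zip(("bond", "angle", "dihedral", "lj", "coulomb", "restraint"), terms))
    e["total"] = sum(terms)
    f[self.frozen] = 0.0
    return e, (f if want_forces else None)


EnergySystem._evaluate_numba = _evaluate_numba  # noqa: E305


# ---------------------------------------------------------------------
# Thin functional wrappers
# ---------------------------------------------------------------------

def total_energy(
    model: ComplexModel,
    params: ForceFieldParameters,
    restraints: RestraintSet | None = None,
    energy_model: EnergyModel | None = None,
) -> dict[str, float]:
    """One-shot energy breakdown of a model (compiles a fresh system)."""
    return EnergySystem(model, params, restraints, energy_model).energy()


def forces(
    model: ComplexModel,
    params: ForceFieldParameters,
    restraints: RestraintSet | None = None,
    energy_model: EnergyModel | None = None,
) -> np.ndarray:
    """One-shot analytic forces on all atoms (zero on frozen atoms)."""
    return EnergySystem(model, params, restraints, energy_model).forces()
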