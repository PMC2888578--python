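"""Energy model: parameters, neutralization, energies, forces."""

import numpy as np
import pytest

from pepsa.forcefield import (
    COULOMB_CONSTANT,
    EnergyModel,
    EnergySystem,
    ParameterizationError,
    RestraintSet,
    assign_charges,
    load_parameters,
    neutralize_charges,
    total_energy,
)
from pepsa.pepbuild import build_peptide
from pepsa.structure import AtomRecord, ComplexModel, assign_mobility, cap_termini


def _bead_pair(distance, res_name="SCP"):
    atoms = [
        AtomRecord(1, "N1" if res_name == "SCP" else "C1", "N", 1, res_name, "S",
                   np.zeros(3)),
        AtomRecord(2, "N1" if res_name == "SCP" else "C1", "N", 2, res_name, "S",
                   np.array([distance, 0.0, 0.0])),
    ]
    return ComplexModel(atoms=atoms, scaffold_residues=[])


class TestParameterFile:
    def test_sections_complete(self, params):
        assert ("GLU", "standard") in params.residues
        assert ("GLU", "neutral") in params.residues
        assert ("PTR", "monoanionic") in params.residues
        assert params.options["scale_ee_14"] == 1.2

    def test_residue_net_charges_are_integers(self, params):
        for (name, form), table in params.residues.items():
            if name in ("SCB", "SCP", "SCN"):  # scaffold beads carry design charges
                continue
            net = sum(q for _, q in table.values())
            assert net == pytest.approx(round(net), abs=1e-9), (name, form)

    def test_with_type_eps(self, params):
        modified = params.with_type_eps("XB", 3.5)
        assert modified.atom_types["XB"][1] == 3.5
        assert params.atom_types["XB"][1] != 3.5  # original untouched


class TestNeutralization:
    def test_glutamate_neutralized(self, params):
        pep = cap_termini(build_peptide(["PTR", "GLU", "GLU", "ILE"]))
        model = neutralize_charges(pep, params)
        for ri in model.residue_indices():
            if model.residue_name(ri) == "GLU":
                net = sum(a.charge for a in model.atoms if a.residue_index == ri)
                assert net == pytest.approx(0.0, abs=1e-9)

    def test_kept_arginine_stays_charged(self, params):
        pep = cap_termini(build_peptide(["PTR", "ARG", "ARG", "ILE"]))
        arg_residues = [ri for ri in pep.residue_indices()
                        if pep.residue_name(ri) == "ARG"]
        model = neutralize_charges(pep, params, keep_charged=(arg_residues[1],))
        nets = {
            ri: sum(a.charge for a in model.atoms if a.residue_index == ri)
            for ri in arg_residues
        }
        assert nets[arg_residues[0]] == pytest.approx(0.0, abs=1e-9)
        assert nets[arg_residues[1]] == pytest.approx(+1.0, abs=1e-9)

    def test_total_charge_is_ptyr_plus_kept(self, params):
        # with both pocket arginines kept, everything else neutral:
        # total = q(PTR) + 2
        pep = cap_termini(build_peptide(["PTR", "ARG", "ARG", "ILE"]))
        args = [ri for ri in pep.residue_indices() if pep.residue_name(ri) == "ARG"]
        model = neutralize_charges(pep, params, keep_charged=tuple(args))
        ptr_net = sum(
            q for _, q in params.residues[("PTR", "standard")].values()
        )
        assert model.charges.sum() == pytest.approx(ptr_net + 2.0, abs=1e-9)

    def test_monoanionic_ptyr_option(self, params):
        pep = cap_termini(build_peptide(["PTR", "GLU", "ILE"]))
        model = neutralize_charges(pep, params, ptr_form="monoanionic")
        assert model.charges.sum() == pytest.approx(-1.0, abs=1e-9)

    def test_missing_exception_residue_rejected(self, params):
        pep = cap_termini(build_peptide(["PTR", "GLU", "ILE"]))
        with pytest.raises(ParameterizationError, match="99"):
            neutralize_charges(pep, params, keep_charged=(99,))


class TestEnergies:
    def test_coulomb_pair_law(self, params):
        # two +1 charges 2 Å apart under eps = R: 332.0636 / 2^2
        model = assign_charges(_bead_pair(2.0), params)
        e = total_energy(model, params)
        assert e["coulomb"] == pytest.approx(COULOMB_CONSTANT / 4.0, abs=1e-10)

    def test_lj_minimum_is_minus_eps(self, params):
        model = assign_charges(_bead_pair(2.0, res_name="SCB"), params)
        rstar, eps = params.atom_types["XB"]
        model.atoms[1].position = np.array([2 * rstar, 0.0, 0.0])
        e = total_energy(model, params)
        assert e["lj"] == pytest.approx(-eps, rel=1e-12)

    def test_restraint_convention(self, params):
        model = assign_charges(_bead_pair(30.0, res_name="SCB"), params)
        restraints = RestraintSet(np.array([0]), np.array([[1.0, 0.0, 0.0]]), k=25.0)
        e = total_energy(model, params, restraints=restraints)
        assert e["restraint"] == pytest.approx(25.0)  # E = k d^2, d = 1 Å

    def test_cutoff_excludes_distant_pairs(self, params):
        near = total_energy(assign_charges(_bead_pair(2.0), params), params)
        far = total_energy(assign_charges(_bead_pair(13.0), params), params)
        assert near["coulomb"] > 0
        assert far["coulomb"] == 0.0

    def test_cutoff_does_not_touch_bonded_terms(self, toy):
        e12 = total_energy(toy.model, toy.params, energy_model=EnergyModel(cutoff=12.0))
        e24 = total_energy(toy.model, toy.params, energy_model=EnergyModel(cutoff=24.0))
        for term in ("bond", "angle", "dihedral", "restraint"):
            assert e12[term] == pytest.approx(e24[term], abs=1e-12)
        assert e12["lj"] != pytest.approx(e24["lj"])

    def test_rigid_motion_invariance(self, capped_peptide, params, rng):
        from pepsa.geometry import apply_transform
        from test_geometry import random_rotation

        system = EnergySystem(capped_peptide, params,
                              restraints=RestraintSet(np.empty(0, int), np.empty((0, 3))),
                              energy_model=EnergyModel(cutoff=100.0))
        e0 = system.energy()["total"]
        rot = random_rotation(rng)
        moved = apply_transform(capped_peptide.coords, rot, np.array([3.0, -1.0, 7.0]))
        assert system.energy(moved)["total"] == pytest.approx(e0, rel=1e-9)

    def test_missing_parameter_names_types(self, toy):
        broken = toy.params
        broken = type(broken)(
            atom_types={k: v for k, v in broken.atom_types.items() if k != "P"},
            bonds=broken.bonds, angles=broken.angles, dihedrals=broken.dihedrals,
            residues=broken.residues, options=broken.options,
        )
        with pytest.raises(ParameterizationError, match="P"):
            EnergySystem(toy.model, broken)

    def test_frozen_pairs_skipped_by_default(self, toy):
        skipped = total_energy(toy.model, toy.params)
        included = total_energy(toy.model, toy.params,
                                energy_model=EnergyModel(include_frozen_pairs=True))
        # frozen-frozen content shifts the energy by a constant
        assert included["total"] != pytest.approx(skipped["total"])


class TestForces:
    @pytest.mark.parametrize("seed", range(3))
    def test_finite_difference_agreement(self, toy, toy_system, seed):
        rng = np.random.default_rng(seed)
        x = toy.extended_coords + rng.normal(scale=0.03, size=toy.extended_coords.shape)
        f = toy_system.forces(x)
        h = 1e-5
        mobile = np.where(~toy_system.frozen)[0]
        checked = 0
        for _ in range(25):
            i = int(rng.choice(mobile))  # frozen forces are zero by contract
            d = int(rng.integers(0, 3))
            xp, xm = x.copy(), x.copy()
            xp[i, d] += h
            xm[i, d] -= h
            numeric = -(toy_system.energy(xp)["total"] - toy_system.energy(xm)["total"]) / (2 * h)
            if abs(numeric) > 1e-4:
                assert f[i, d] == pytest.approx(numeric, rel=1e-4)
                checked += 1
        assert checked > 10

    def test_frozen_forces_reported_zero(self, toy, toy_system):
        f = toy_system.forces(toy.extended_coords)
        assert np.all(f[toy_system.frozen] == 0.0)

    def test_bonded_pair_newton_third_law(self, params):
        pep = build_peptide(["GLY"])
        pep2 = assign_charges(pep, params)
        system = EnergySystem(pep2, params)
        f = system.forces(pep2.coords)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)

    def test_backends_agree(self, toy):
        numba_sys = EnergySystem(toy.model, toy.params, backend="numba")
        numpy_sys = EnergySystem(toy.model, toy.params, backend="numpy")
        x = toy.compact_coords
        e1, e2 = numba_sys.energy(x), numpy_sys.energy(x)
        for key in e1:
            assert e1[key] == pytest.approx(e2[key], abs=1e-9)
        np.testing.assert_allclose(numba_sys.forces(x), numpy_sys.forces(x), atol=1e-9)
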