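"""Integrator, thermostat, temperature bookkeeping, minimizers."""

import numpy as np
import pytest

from pepsa.dynamics import (
    AKMA,
    KB,
    IntegrationError,
    MDState,
    MinimizationSpec,
    POST_SA_MINIMIZATION,
    PRE_SA_MINIMIZATION,
    Thermostat,
    kinetic_temperature,
    maxwell_boltzmann_velocities,
    minimize_positions,
    run_md,
    verlet_step,
)
from pepsa.forcefield import EnergySystem, assign_charges
from pepsa.pepbuild import build_peptide


class _Harmonic1D:
    """Stub system: one particle in E = k x^2 (AMBER-style convention)."""

    def __init__(self, k):
        self.k = k

    def forces(self, x):
        return -2.0 * self.k * x

    def energy(self, x):
        return {"total": float(self.k * np.sum(x**2))}


def _free_state(x, v, mass=12.0):
    n = len(x)
    return MDState(x, v, np.full(n, mass), np.zeros(n, bool))


class TestVerlet:
    def test_zero_force_straight_line(self):
        system = _Harmonic1D(0.0)
        state = _free_state(np.zeros((1, 3)), np.array([[1.0, 0.0, 0.0]]))
        f = system.forces(state.positions)
        for _ in range(100):
            state, f = verlet_step(state, f, 0.001, system)
        np.testing.assert_allclose(state.positions[0], [0.1, 0.0, 0.0], atol=1e-12)

    def test_oscillator_period_matches_closed_form(self):
        k, m = 100.0, 12.0  # kcal/(mol Å^2), amu
        system = _Harmonic1D(k)
        state = _free_state(np.array([[0.3, 0.0, 0.0]]), np.zeros((1, 3)), mass=m)
        dt = 0.0005  # 0.5 fs
        f = system.forces(state.positions)
        crossings = []
        prev = state.positions[0, 0]
        for step in range(20000):
            state, f = verlet_step(state, f, dt, system)
            x = state.positions[0, 0]
            if prev > 0 >= x:
                crossings.append(state.time)
            prev = x
            if len(crossings) >= 5:
                break
        measured = np.mean(np.diff(crossings))
        expected = 2 * np.pi * np.sqrt(m / (2 * k * AKMA))
        assert measured == pytest.approx(expected, rel=0.01)

    def test_instability_guard(self, toy_minimized):
        system, x0 = toy_minimized
        rng = np.random.default_rng(0)
        v = maxwell_boltzmann_velocities(system.masses, system.frozen, 300.0, rng)
        state = MDState(x0.copy(), v, system.masses, system.frozen)
        with pytest.raises(IntegrationError):
            # absurd timestep -> guard trips on per-step displacement
            run_md(state, system, 300.0, duration=50.0, dt=1.0, sample_stride=1)

    def test_frozen_atoms_never_move(self, toy_minimized):
        system, x0 = toy_minimized
        state = MDState(x0.copy(), np.zeros_like(x0), system.masses, system.frozen,
                        seed=3)
        final, _ = run_md(state, system, 500.0, duration=0.2, dt=0.001)
        np.testing.assert_array_equal(final.positions[system.frozen],
                                      x0[system.frozen])
        assert np.all(final.velocities[system.frozen] == 0.0)


class TestTemperature:
    def test_zero_velocities_zero_kelvin(self, toy_minimized):
        system, x0 = toy_minimized
        state = MDState(x0, np.zeros_like(x0), system.masses, system.frozen)
        assert kinetic_temperature(state) == 0.0

    def test_quadratic_scaling(self, toy_minimized, rng):
        system, x0 = toy_minimized
        v = maxwell_boltzmann_velocities(system.masses, system.frozen, 250.0, rng)
        t1 = kinetic_temperature(MDState(x0, v, system.masses, system.frozen))
        t2 = kinetic_temperature(MDState(x0, v * np.sqrt(2), system.masses, system.frozen))
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_maxwell_boltzmann_sampling(self, rng):
        masses = np.full(1000, 12.0)
        frozen = np.zeros(1000, bool)
        v = maxwell_boltzmann_velocities(masses, frozen, 300.0, rng)
        ke = 0.5 * np.sum(masses[:, None] * v**2) / AKMA
        t = 2 * ke / (3000 * KB)
        assert t == pytest.approx(300.0, abs=15.0)

    def test_no_mobile_atoms_undefined(self):
        state = MDState(np.zeros((2, 3)), np.zeros((2, 3)), np.ones(2),
                        np.ones(2, bool))
        with pytest.raises(ValueError, match="temperature"):
            kinetic_temperature(state)

    def test_frozen_excluded_from_dof(self, toy_minimized, rng):
        # equipartition bookkeeping: temperature uses mobile atoms only
        system, x0 = toy_minimized
        v = maxwell_boltzmann_velocities(system.masses, system.frozen, 300.0, rng)
        state = MDState(x0, v, system.masses, system.frozen)
        n_mobile = int(np.sum(~system.frozen))
        ke = 0.5 * np.sum(system.masses[:, None] * state.velocities**2) / AKMA
        assert kinetic_temperature(state) == pytest.approx(
            2 * ke / (3 * n_mobile * KB), rel=1e-12
        )


class TestThermostat:
    def test_converges_to_target(self, toy_minimized):
        system, x0 = toy_minimized
        state = MDState(x0.copy(), np.zeros_like(x0), system.masses, system.frozen,
                        seed=11)
        _, traj = run_md(state, system, 300.0, duration=10.0, dt=0.001,
                         sample_stride=100)
        second_half = np.array(traj.temperatures)[len(traj.temperatures) // 2:]
        assert 285.0 <= second_half.mean() <= 315.0

    def test_converges_from_hot_start(self, toy_minimized):
        system, x0 = toy_minimized
        rng = np.random.default_rng(5)
        v = maxwell_boltzmann_velocities(system.masses, system.frozen, 900.0, rng)
        state = MDState(x0.copy(), v, system.masses, system.frozen)
        _, traj = run_md(state, system, 300.0, duration=5.0, dt=0.001,
                         sample_stride=100, thermostat=Thermostat(300.0))
        second_half = np.array(traj.temperatures)[len(traj.temperatures) // 2:]
        assert second_half.mean() == pytest.approx(300.0, rel=0.05)

    def test_degenerate_duration_executes_one_step(self, toy_minimized):
        system, x0 = toy_minimized
        state = MDState(x0.copy(), np.zeros_like(x0), system.masses, system.frozen,
                        seed=0)
        final, _ = run_md(state, system, 300.0, duration=0.001, dt=0.001)
        assert final.time == pytest.approx(0.001)

    def test_heating_protocol_reaches_3000k(self, toy_minimized):
        from pepsa.annealing import heat

        system, x0 = toy_minimized
        state = MDState(x0.copy(), np.zeros_like(x0), system.masses, system.frozen,
                        seed=2)
        state = heat(state, system, stages=((1000.0, 0.3), (2000.0, 0.3)),
                     rng=np.random.default_rng(2))
        _, traj = run_md(state, system, 3000.0, duration=0.6, dt=0.0005,
                         sample_stride=50)
        # scaled stages are a few thermostat times long; judge the
        # equilibrated part of the final stage
        final_half = np.array(traj.temperatures)[len(traj.temperatures) // 2:]
        assert final_half.mean() == pytest.approx(3000.0, rel=0.10)


class TestMinimize:
    @staticmethod
    def _bonded_dimer(params, distance):
        """Single NME residue: exactly one harmonic bond (N-CH3)."""
        from pepsa.structure import AtomRecord, ComplexModel

        atoms = [
            AtomRecord(1, "N", "N", 1, "NME", "P", np.zeros(3)),
            AtomRecord(2, "CH3", "C", 1, "NME", "P",
                       np.array([distance, 0.0, 0.0])),
        ]
        model = assign_charges(
            ComplexModel(atoms=atoms, peptide_residues=[1]), params
        )
        return model, EnergySystem(model, params)

    def test_fixed_point_at_minimum(self, params):
        model, system = self._bonded_dimer(params, 1.449)  # r0 of N-CT
        x0 = model.coords
        x_min, _ = minimize_positions(system, x0, MinimizationSpec(50, 100))
        assert np.linalg.norm(x_min - x0) < 1e-6

    def test_perturbed_dimer_returns_to_equilibrium(self, params):
        model, system = self._bonded_dimer(params, 2.1)  # stretched
        x_min, trace = minimize_positions(system, model.coords,
                                          MinimizationSpec(100, 200))
        assert np.linalg.norm(x_min[1] - x_min[0]) == pytest.approx(1.449, abs=1e-3)
        assert trace[-1] <= trace[0]

    def test_trace_non_increasing(self, toy, toy_system):
        _, trace = minimize_positions(toy_system, toy.extended_coords,
                                      PRE_SA_MINIMIZATION)
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-6)

    def test_default_protocol_specs(self):
        assert (PRE_SA_MINIMIZATION.sd_steps, PRE_SA_MINIMIZATION.cg_steps) == (250, 750)
        assert (POST_SA_MINIMIZATION.sd_steps, POST_SA_MINIMIZATION.cg_steps) == (200, 600)

    def test_nonfinite_start_rejected(self, toy_system, toy):
        bad = toy.extended_coords.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            minimize_positions(toy_system, bad, PRE_SA_MINIMIZATION)

    def test_frozen_unmoved_by_minimizer(self, toy, toy_system):
        x_min, _ = minimize_positions(toy_system, toy.compact_coords,
                                      POST_SA_MINIMIZATION)
        np.testing.assert_array_equal(x_min[toy_system.frozen],
                                      toy.compact_coords[toy_system.frozen])


class TestConservation:
    def test_nve_secular_drift_small_and_second_order(self, toy_minimized):
        system, x0 = toy_minimized
        rng = np.random.default_rng(42)
        v = maxwell_boltzmann_velocities(system.masses, system.frozen, 300.0, rng)

        def drift(dt, duration):
            state = MDState(x0.copy(), v.copy(), system.masses, system.frozen)
            _, traj = run_md(state, system, None, duration, dt=dt, sample_stride=50)
            ke = np.array(traj.temperatures) * (3 * state.n_mobile * KB) / 2
            pe = np.array([e["total"] for e in traj.energies])
            e = ke + pe
            q = max(1, len(e) // 4)
            return abs(e[-q:].mean() - e[:q].mean()) / abs(e.mean()), e

        d_1fs, energies = drift(0.001, 10.0)
        assert d_1fs < 1e-3
        # oscillation about the mean is bounded (no runaway)
        assert (energies.max() - energies.min()) / abs(energies.mean()) < 5e-3
        # order of accuracy: peak-to-peak error shrinks when dt halves
        _, e_half = drift(0.0005, 2.0)
        _, e_full = drift(0.001, 2.0)
        p2p = lambda e: (e.max() - e.min()) / abs(e.mean())
        assert p2p(e_half) < p2p(e_full)
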