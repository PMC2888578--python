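"""Velocity-Verlet dynamics, weak-coupling thermostat and minimizers.

Unit system (AMBER-like "AKMA"): lengths in Å, energies in kcal/mol,
masses in amu, time in ps.  One kcal/mol equals 418.4 amu·Å²/ps², so
accelerations are ``F / m * 418.4`` Å/ps².

Frozen atoms are never propagated by anything in this module; the
temperature is defined by equipartition over the 3N degrees of freedom
of the *mobile* (free + restrained) atoms only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .forcefield import EnergySystem

__all__ = [
    "KB",
    "AKMA",
    "MDState",
    "MinimizationSpec",
    "Thermostat",
    "maxwell_boltzmann_velocities",
    "kinetic_temperature",
    "kinetic_energy",
    "verlet_step",
    "run_md",
    "minimize_positions",
    "minimize",
    "IntegrationError",
    "PRE_SA_MINIMIZATION",
    "POST_SA_MINIMIZATION",
]

KB = 0.0019872041  # kcal/(mol·K)
AKMA = 418.4  # (amu·Å²/ps²) per (kcal/mol)


class IntegrationError(RuntimeError):
    pass


@dataclass
class MinimizationSpec:
    """Staged minimization: steepest-descent steps then conjugate-gradient steps."""

    sd_steps: int = 250
    cg_steps: int = 750
    tolerance: float = 1e-4  # gradient norm, kcal/(mol·Å)

    def __post_init__(self):
        if self.sd_steps < 0 or self.cg_steps < 0:
            raise ValueError("step counts must be non-negative")


#: protocol defaults: geometry relaxation before annealing and the
#: final quench applied to every cooled replica
PRE_SA_MINIMIZATION = MinimizationSpec(sd_steps=250, cg_steps=750)
POST_SA_MINIMIZATION = MinimizationSpec(sd_steps=200, cg_steps=600)


@dataclass
class Thermostat:
    """Berendsen-style velocity-rescaling weak coupling."""

    target: float  # K
    tau: float = 0.1  # ps

    def scale_factor(self, current_t: float, dt: float) -> float:
        if current_t <= 0:
            return 1.0
        lam2 = 1.0 + (dt / self.tau) * (self.target / current_t - 1.0)
        return float(np.sqrt(np.clip(lam2, 0.64, 1.5625)))


@dataclass
class MDState:
    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    frozen: np.ndarray  # boolean mask
    time: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.velocities = np.asarray(self.velocities, float)
        self.masses = np.asarray(self.masses, float)
        self.frozen = np.asarray(self.frozen, bool)
        self.velocities[self.frozen] = 0.0

    @property
    def n_mobile(self) -> int:
        return int(np.sum(~self.frozen))

    @classmethod
    def from_system(cls, system: EnergySystem, seed: int | None = None,
                    temperature: float | None = None) -> "MDState":
        pos = system.model_ref.coords
        vel = np.zeros_like(pos)
        state = cls(pos, vel, system.masses, system.frozen, seed=seed)
        if temperature is not None:
            rng = np.random.default_rng(seed)
            state.velocities = maxwell_boltzmann_velocities(
                state.masses, state.frozen, temperature, rng
            )
        return state

    def copy(self) -> "MDState":
        return MDState(
            self.positions.copy(), self.velocities.copy(), self.masses,
            self.frozen, self.time, self.seed,
        )


def maxwell_boltzmann_velocities(masses, frozen, temperature, rng) -> np.ndarray:
    sigma = np.sqrt(KB * temperature * AKMA / np.asarray(masses, float))
    v = rng.normal(size=(len(masses), 3)) * sigma[:, None]
    v[np.asarray(frozen, bool)] = 0.0
    return v


def kinetic_energy(state: MDState) -> float:
    """Kinetic energy in kcal/mol."""
    v2 = np.sum(state.velocities**2, axis=1)
    return float(0.5 * np.sum(state.masses * v2) / AKMA)


def kinetic_temperature(state: MDState) -> float:
    """Instantaneous temperature from equipartition over mobile atoms."""
    n_dof = 3 * state.n_mobile
    if n_dof == 0:
        raise ValueError("temperature undefined: no mobile atoms")
    return 2.0 * kinetic_energy(state) / (n_dof * KB)


def verlet_step(state: MDState, forces: np.ndarray, dt: float,
                system: EnergySystem) -> tuple[MDState, np.ndarray]:
    """One velocity-Verlet step; returns the new state and the new forces.

    Frozen atoms are untouched.  A displacement larger than 2 Å in a
    single step trips the instability guard.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    mobile = ~state.frozen
    acc = np.zeros_like(state.positions)
    acc[mobile] = forces[mobile] / state.masses[mobile, None] * AKMA

    new = state.copy()
    step = state.velocities * dt + 0.5 * acc * dt**2
    max_step = float(np.max(np.linalg.norm(step, axis=1))) if len(step) else 0.0
    if not np.isfinite(max_step) or max_step > 2.0:
        raise IntegrationError(
            f"integration unstable: max per-step displacement {max_step:.2f} Å"
        )
    new.positions = state.positions + np.where(mobile[:, None], step, 0.0)
    new_forces = system.forces(new.positions)
    new_acc = np.zeros_like(acc)
    new_acc[mobile] = new_forces[mobile] / state.masses[mobile, None] * AKMA
    new.velocities = np.where(
        mobile[:, None], state.velocities + 0.5 * (acc + new_acc) * dt, 0.0
    )
    new.time = state.time + dt
    return new, new_forces


@dataclass
class Trajectory:
    times: list[float] = field(default_factory=list)
    temperatures: list[float] = field(default_factory=list)
    energies: list[dict] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)


def run_md(
    state: MDState,
    system: EnergySystem,
    t_target: float,
    duration: float,
    dt: float = 0.001,
    thermostat: Thermostat | None = None,
    sample_stride: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[MDState, Trajectory]:
    """Thermostatted (or NVE if ``thermostat`` is explicitly None-capable) run.

    ``sample_stride`` > 0 stores every that-many-th frame in the returned
    :class:`Trajectory`.  If the state is cold (T ≈ 0) and a target
    temperature is requested, velocities are drawn from the
    Maxwell-Boltzmann distribution first.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if thermostat is None and t_target is not None:
        thermostat = Thermostat(target=t_target)

    state = state.copy()
    if thermostat is not None and kinetic_temperature(state) < 1e-9:
        rng = rng or np.random.default_rng(state.seed)
        state.velocities = maxwell_boltzmann_velocities(
            state.masses, state.frozen, thermostat.target, rng
        )

    n_steps = max(1, int(round(duration / dt)))
    forces = system.forces(state.positions)
    traj = Trajectory()
    e0 = system.energy(state.positions)["total"]
    for step_i in range(n_steps):
        state, forces = verlet_step(state, forces, dt, system)
        if thermostat is not None:
            t_now = kinetic_temperature(state)
            state.velocities *= thermostat.scale_factor(t_now, dt)
        if sample_stride and (step_i + 1) % sample_stride == 0:
            e = system.energy(state.positions)
            if not np.isfinite(e["total"]) or e["total"] > abs(e0) + 1e6:
                raise IntegrationError("potential energy exploded during MD")
            traj.times.append(state.time)
            traj.temperatures.append(kinetic_temperature(state))
            traj.energies.append(e)
            traj.positions.append(state.positions.copy())
    return state, traj


# ---------------------------------------------------------------------
# Minimization
# ---------------------------------------------------------------------

def minimize_positions(
    system: EnergySystem, positions: np.ndarray, spec: MinimizationSpec
) -> tuple[np.ndarray, list[float]]:
    """Steepest descent then conjugate gradient on the mobile coordinates.

    Returns the relaxed coordinates and the energy trace (one entry per
    accepted step, monotonically non-increasing within line-search
    tolerance).  Frozen atoms do not move.
    """
    x = np.array(positions, float)
    mobile = ~system.frozen
    e = system.energy(x)["total"]
    if not np.isfinite(e):
        raise ValueError("non-finite energy at minimization start")
    trace = [e]

    # --- steepest descent with adaptive step size
    alpha = 1e-4
    for _ in range(spec.sd_steps):
        f = system.forces(x)
        gnorm = np.linalg.norm(f[mobile])
        if gnorm < spec.tolerance:
            break
        direction = f / max(gnorm, 1e-30)
        accepted = False
        for _try in range(20):
            x_new = x.copy()
            x_new[mobile] += alpha * gnorm * direction[mobile]
            e_new = system.energy(x_new)["total"]
            if e_new <= e:
                x, e = x_new, e_new
                alpha *= 1.2
                accepted = True
                break
            alpha *= 0.5
        trace.append(e)
        if not accepted:
            break

    # --- conjugate gradient (scipy) on flattened mobile coordinates
    if spec.cg_steps > 0:
        idx = np.where(mobile)[0]

        def fun(flat):
            xx = x.copy()
            xx[idx] = flat.reshape(-1, 3)
            e_val, f_val = system.energy_forces(xx)
            return e_val["total"], -f_val[idx].ravel()

        def cb(flat):
            trace.append(fun(flat)[0])

        res = _scipy_minimize(
            fun,
            x[idx].ravel(),
            jac=True,
            method="CG",
            callback=cb,
            options={"maxiter": spec.cg_steps, "gtol": spec.tolerance},
        )
        x[idx] = res.x.reshape(-1, 3)
        trace.append(system.energy(x)["total"])
    return x, trace


def minimize(model, params, restraints=None, spec: MinimizationSpec | None = None,
             energy_model=None):
    """Relax a :class:`~pepsa.structure.ComplexModel` in place-free style.

    Returns ``(relaxed_model, energy_trace)``; the final energy breakdown
    is available via :func:`pepsa.forcefield.total_energy` on the result.
    """
    spec = spec or PRE_SA_MINIMIZATION
    system = EnergySystem(model, params, restraints, energy_model)
    x, trace = minimize_positions(system, model.coords, spec)
    out = model.copy()
    out.set_coords(x)
    out.needs_minimization = False
    return out, trace
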