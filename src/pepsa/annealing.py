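"""Simulated-annealing protocol for restrained peptide sampling.

The full protocol mirrors classical restrained annealing of a flexible
ligand on a rigid receptor: initial minimization, staged heating to a
high sampling temperature (3000 K by default), collection of replicas
from the continuous high-temperature trajectory at regular intervals,
geometric ("logarithmic") cooling of every replica — the thermostat
set-point is multiplied by a factor x (default 0.8) at each step until
it reaches the final temperature — and a final quench minimization.

Replica independence is strict: each replica carries its own seed
(derived from the master seed and the replica index) and its results do
not depend on the order in which replicas are processed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import ca_coords, ca_rmsd
from .dynamics import (
    POST_SA_MINIMIZATION,
    MDState,
    MinimizationSpec,
    IntegrationError,
    Thermostat,
    maxwell_boltzmann_velocities,
    minimize_positions,
    run_md,
)
from .forcefield import EnergySystem
from .structure import ComplexModel

__all__ = [
    "CoolingSchedule",
    "Replica",
    "ReplicaEnsemble",
    "build_schedule",
    "heat",
    "generate_replicas",
    "choose_sampling_interval",
    "anneal",
    "ScheduleError",
]

#: full-scale protocol constants
DEFAULT_T0 = 3000.0
DEFAULT_FACTOR = 0.8
DEFAULT_T_FINAL = 300.0
DEFAULT_REPLICAS = 50
#: timestep policy: smaller step at sampling temperatures
DT_HOT = 0.0005  # ps, T >= 1000 K
DT_COLD = 0.001  # ps


class ScheduleError(ValueError):
    pass


@dataclass
class CoolingSchedule:
    t0: float = DEFAULT_T0
    factor: float = DEFAULT_FACTOR
    t_final: float = DEFAULT_T_FINAL
    temperatures: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.temperatures:
            temps = np.asarray(self.temperatures)
            if np.any(np.diff(temps) >= 0):
                raise ScheduleError("schedule temperatures must decrease strictly")
            if abs(temps[-1] - self.t_final) > 1e-9:
                raise ScheduleError("schedule must end at t_final")

    @property
    def n_levels(self) -> int:
        return len(self.temperatures)


def build_schedule(
    t0: float = DEFAULT_T0,
    factor: float = DEFAULT_FACTOR,
    t_final: float = DEFAULT_T_FINAL,
) -> CoolingSchedule:
    """Geometric cooling levels ``t0 * x^k`` clamped to end at ``t_final``.

    ``build_schedule(3000, 0.8, 300)`` gives the 12 levels
    3000, 2400, ..., 322.14, 300.
    """
    if not (t0 > t_final > 0):
        raise ScheduleError("need t0 > t_final > 0")
    if not (0 < factor < 1):
        raise ScheduleError("cooling factor must lie in (0, 1)")
    temps = []
    t = t0
    while t > t_final + 1e-9:
        temps.append(t)
        t *= factor
    temps.append(t_final)
    return CoolingSchedule(t0=t0, factor=factor, t_final=t_final, temperatures=temps)


@dataclass
class Replica:
    index: int
    seed: tuple[int, int]
    positions: np.ndarray
    energy: dict | None = None
    rmsd_start_full: float | None = None
    rmsd_start_segment: float | None = None
    failed: bool = False
    temperature_history: list[float] = field(default_factory=list)


@dataclass
class ReplicaEnsemble:
    model: ComplexModel
    replicas: list[Replica]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.replicas) < 1:
            raise ValueError("ensemble needs at least one replica")

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def active(self) -> list[Replica]:
        return [r for r in self.replicas if not r.failed]

    def coordinate_stack(self) -> np.ndarray:
        return np.stack([r.positions for r in self.active()])

    def statistics(self, segment=None) -> dict:
        """Mean ± sd CA-RMSD from the start and the energy range."""
        start_ca = ca_coords(self.model, segment=segment or "full")
        rmsds = [
            ca_rmsd(ca_coords(self.model, r.positions, segment or "full"), start_ca)
            for r in self.active()
        ]
        energies = [r.energy["total"] for r in self.active() if r.energy is not None]
        out = {
            "rmsd_mean": float(np.mean(rmsds)),
            "rmsd_sd": float(np.std(rmsds)),
            "rmsd_range": (float(np.min(rmsds)), float(np.max(rmsds))),
            "n_failed": self.n_replicas - len(self.active()),
        }
        if energies:
            out.update(
                energy_mean=float(np.mean(energies)),
                energy_sd=float(np.std(energies)),
                energy_range=(float(np.min(energies)), float(np.max(energies))),
            )
        return out


# ---------------------------------------------------------------------
# Protocol stages
# ---------------------------------------------------------------------

def heat(
    state: MDState,
    system: EnergySystem,
    stages: list[tuple[float, float]] = ((1000.0, 10.0), (2000.0, 10.0), (3000.0, 10.0)),
    rng: np.random.Generator | None = None,
) -> MDState:
    """Staged heating: a linear ramp of set-points (default 3 x 10 ps to 3000 K)."""
    rng = rng or np.random.default_rng(state.seed)
    for t_target, duration in stages:
        dt = DT_HOT if t_target >= 1000 else DT_COLD
        state, _ = run_md(state, system, t_target, duration, dt=dt, rng=rng)
    return state


def generate_replicas(
    state: MDState,
    system: EnergySystem,
    model: ComplexModel,
    n: int = DEFAULT_REPLICAS,
    interval: float = 2.5,
    master_seed: int = 0,
    t_sample: float = DEFAULT_T0,
) -> ReplicaEnsemble:
    """Collect ``n`` snapshots from continued high-temperature dynamics.

    The sampling trajectory is one continuous run at ``t_sample``;
    a snapshot is taken every ``interval`` ps.  Each snapshot becomes a
    replica carrying its own derived seed and its CA-RMSD from the
    starting model.
    """
    if n < 1:
        raise ValueError("need at least one replica")
    if interval <= 0:
        raise ValueError("sampling interval must be positive")
    dt = DT_HOT if t_sample >= 1000 else DT_COLD
    stride = max(1, int(round(interval / dt)))
    _, traj = run_md(
        state, system, t_sample, duration=n * interval, dt=dt,
        sample_stride=stride, rng=np.random.default_rng(master_seed),
    )
    start_full = ca_coords(model)
    replicas = []
    for i, pos in enumerate(traj.positions[:n]):
        replicas.append(
            Replica(
                index=i,
                seed=(master_seed, i),
                positions=pos,
                rmsd_start_full=ca_rmsd(ca_coords(model, pos), start_full),
            )
        )
    if len(replicas) < n:
        raise RuntimeError("sampling trajectory yielded fewer snapshots than requested")
    return ReplicaEnsemble(
        model=model,
        replicas=replicas,
        provenance={"t_sample": t_sample, "interval_ps": interval,
                    "master_seed": master_seed, "n": n},
    )


def choose_sampling_interval(
    candidates: list[float],
    state: MDState,
    system: EnergySystem,
    model: ComplexModel,
    n_probe: int = 8,
    master_seed: int = 0,
) -> float:
    """Pick the snapshot interval maximizing conformational spread.

    Each candidate is scored on a short trial ensemble by
    ``minmax(mean pairwise CA-RMSD) + minmax(mean CA-RMSD to start)``;
    ties break to the smaller (cheaper) interval.
    """
    if not candidates:
        raise ValueError("no candidate intervals supplied")
    if len(candidates) == 1:
        return float(candidates[0])
    spread, drift = [], []
    start_ca = ca_coords(model)
    for cand in candidates:
        ens = generate_replicas(
            state.copy(), system, model, n=n_probe, interval=cand,
            master_seed=master_seed,
        )
        cas = [ca_coords(model, r.positions) for r in ens.replicas]
        pair = [
            ca_rmsd(cas[i], cas[j])
            for i in range(len(cas))
            for j in range(i + 1, len(cas))
        ]
        spread.append(float(np.mean(pair)) if pair else 0.0)
        drift.append(float(np.mean([ca_rmsd(c, start_ca) for c in cas])))

    def _minmax(v):
        v = np.asarray(v)
        rng_ = v.max() - v.min()
        return np.zeros_like(v) if rng_ < 1e-12 else (v - v.min()) / rng_

    score = _minmax(spread) + _minmax(drift)
    order = sorted(range(len(candidates)), key=lambda i: (-score[i], candidates[i]))
    return float(candidates[order[0]])


def anneal(
    ensemble: ReplicaEnsemble,
    system: EnergySystem,
    schedule: CoolingSchedule,
    duration_per_step: float,
    post_minimization: MinimizationSpec = POST_SA_MINIMIZATION,
    segment=None,
) -> ReplicaEnsemble:
    """Cool every replica through the schedule and quench-minimize it.

    Each replica is annealed independently (fresh Maxwell-Boltzmann
    velocities at the top temperature from its own seed, one
    thermostatted run of ``duration_per_step`` ps per level).  A replica
    whose integration blows up is flagged failed and excluded from the
    statistics; the others are unaffected.
    """
    if duration_per_step < 0:
        raise ValueError("duration must be non-negative")
    out_replicas = []
    start_full = ca_coords(ensemble.model)
    start_seg = ca_coords(ensemble.model, segment=segment) if segment else None
    for rep in ensemble.replicas:
        rng = np.random.default_rng(rep.seed)
        positions = rep.positions.copy()
        state = MDState(
            positions,
            maxwell_boltzmann_velocities(
                system.masses, system.frozen, schedule.temperatures[0]
                if schedule.temperatures else 0.0, rng,
            ),
            system.masses,
            system.frozen,
        )
        new = Replica(index=rep.index, seed=rep.seed, positions=positions)
        try:
            if duration_per_step > 0:
                for t_level in schedule.temperatures:
                    dt = DT_HOT if t_level >= 1000 else DT_COLD
                    state, _ = run_md(
                        state, system, t_level, duration_per_step, dt=dt,
                        thermostat=Thermostat(target=t_level), rng=rng,
                    )
                    new.temperature_history.append(t_level)
            x_min, _ = minimize_positions(system, state.positions, post_minimization)
            new.positions = x_min
            new.energy = system.energy(x_min)
            new.rmsd_start_full = ca_rmsd(ca_coords(ensemble.model, x_min), start_full)
            if start_seg is not None:
                new.rmsd_start_segment = ca_rmsd(
                    ca_coords(ensemble.model, x_min, segment), start_seg
                )
        except IntegrationError:
            new.failed = True
        out_replicas.append(new)
    return ReplicaEnsemble(
        model=ensemble.model,
        replicas=out_replicas,
        provenance={
            **ensemble.provenance,
            "schedule": list(schedule.temperatures),
            "duration_per_step_ps": duration_per_step,
            "post_minimization": (post_minimization.sd_steps, post_minimization.cg_steps),
        },
    )
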