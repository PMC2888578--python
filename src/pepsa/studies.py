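"""Desk-scale simulation studies on the synthetic complex.

These are the scaled-down counterparts of the full-scale protocol:
cooling-rate sweeps on the toy two-basin complex, the pTyr+3
hydrophobic-series sweep, and IC50 parameter-recovery simulations.
Each study is a pure function of its settings and a master seed.

Problem sizes (8 replicas per batch, 0.05–1 ps cooling levels, a 55-atom
complex) are chosen so a full sweep runs in minutes on a single core
while preserving the protocol structure: minimize → heat → sample →
cool → minimize.
"""

from __future__ import annotations

import numpy as np

from .annealing import anneal, build_schedule, generate_replicas, heat
from .binding import fit_ic50
from .dynamics import MDState, PRE_SA_MINIMIZATION, minimize_positions
from .forcefield import EnergySystem
from .synthetic import (
    POCKET_DEPTH_SERIES,
    TitrationTruth,
    ToyComplexSpec,
    make_titration,
    make_toy_complex,
)

__all__ = [
    "TOY_HEATING_STAGES",
    "TOY_DURATIONS",
    "anneal_toy_batch",
    "cooling_rate_study",
    "pocket_series_study",
    "ic50_recovery_study",
]

#: scaled heating protocol (three stages to 3000 K, as at full scale)
TOY_HEATING_STAGES = ((1000.0, 0.3), (2000.0, 0.3), (3000.0, 0.3))
#: desk-scale analogues of the 10/50/500 ps-per-level cooling rates
TOY_DURATIONS = (0.02, 0.2, 1.0)


def anneal_toy_batch(toy, durations, n_replicas: int, seed: int):
    """One seed-batch: minimize, heat, sample, cool at each duration.

    Returns ``{duration: (labels, energies)}`` over non-failed replicas.
    """
    system = EnergySystem(toy.model, toy.params)
    x0, _ = minimize_positions(system, toy.extended_coords, PRE_SA_MINIMIZATION)
    model = toy.model.copy()
    model.set_coords(x0)
    model.reference_positions = x0.copy()
    system = EnergySystem(model, toy.params)

    state = MDState(x0.copy(), np.zeros_like(x0), system.masses, system.frozen,
                    seed=seed)
    state = heat(state, system, stages=TOY_HEATING_STAGES,
                 rng=np.random.default_rng(seed))
    ensemble = generate_replicas(state, system, model, n=n_replicas,
                                 interval=0.25, master_seed=seed)
    schedule = build_schedule()
    out = {}
    for duration in durations:
        cooled = anneal(ensemble, system, schedule, duration)
        labels = [toy.label_basin(r.positions) for r in cooled.active()]
        energies = [r.energy["total"] for r in cooled.active()]
        out[duration] = (labels, energies)
    return out


def cooling_rate_study(
    durations=TOY_DURATIONS,
    n_batches: int = 6,
    n_replicas: int = 8,
    master_seed: int = 0,
) -> dict:
    """Global-basin occupancy and mean energy versus cooling rate."""
    toy = make_toy_complex(ToyComplexSpec())
    labels = {d: [] for d in durations}
    energies = {d: [] for d in durations}
    for batch in range(n_batches):
        seed = int(master_seed + 1000 * batch + 1)
        for duration, (lbl, en) in anneal_toy_batch(
            toy, durations, n_replicas, seed
        ).items():
            labels[duration] += lbl
            energies[duration] += en
    return {
        d: {
            "occupancy": labels[d].count("pocket") / len(labels[d]),
            "energy_mean": float(np.mean(energies[d])),
            "energy_sd": float(np.std(energies[d])),
            "n": len(labels[d]),
        }
        for d in durations
    }


def pocket_series_study(
    series: dict[str, float] | None = None,
    n_batches: int = 5,
    n_replicas: int = 8,
    duration: float = 1.0,
    master_seed: int = 0,
) -> dict[str, dict]:
    """Pocket-bound fraction across the pTyr+3 hydrophobic-series analogue."""
    series = series or POCKET_DEPTH_SERIES
    out = {}
    for residue, depth in series.items():
        toy = make_toy_complex(ToyComplexSpec(pocket_depth=depth))
        labels = []
        for batch in range(n_batches):
            seed = int(master_seed + 1000 * batch + 7)
            labels += anneal_toy_batch(toy, (duration,), n_replicas, seed)[duration][0]
        out[residue] = {
            "depth": depth,
            "fraction": labels.count("pocket") / len(labels),
            "n": len(labels),
        }
    return out


def ic50_recovery_study(
    ic50s_molar=(0.5e-6, 1e-6, 2e-6, 5e-6, 8e-6),
    noise_fraction: float = 0.05,
    n_seeds: int = 100,
    master_seed: int = 0,
) -> dict:
    """Median relative IC50 error across a noisy synthetic titration grid."""
    errors = []
    for i, true_ic50 in enumerate(ic50s_molar):
        for s in range(n_seeds):
            truth = TitrationTruth(
                ic50=true_ic50,
                noise_sd=noise_fraction * (200.0 - 60.0),
                seed=int(master_seed + 977 * i + s),
            )
            fitted = fit_ic50(make_titration(truth), n_bootstrap=0).ic50
            errors.append(abs(fitted - true_ic50) / true_ic50)
    return {
        "median_relative_error": float(np.median(errors)),
        "n": len(errors),
    }
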