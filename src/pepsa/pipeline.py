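"""End-to-end orchestration: build → anneal → cluster → report.

This module is the library core behind the command-line interface.  It
wires the protocol stages together, carries provenance (config hash,
seeds, package version) and writes the artifact files (multi-model PDB,
per-replica CSV, JSON reports).

The full-scale protocol (3000 K, 50 replicas, 10–500 ps per cooling
level) and the desk-scale toy protocol (same structure, durations
scaled into the 0.05–1 ps range so a full sweep runs in minutes on one
core) are both expressed as :class:`SAProtocol` instances.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    ca_coords,
    ca_rmsd,
    classify_clusters,
    joint_rmsd_energy_clusters,
    nmrclust,
    representative,
)
from .annealing import (
    CoolingSchedule,
    ReplicaEnsemble,
    anneal,
    build_schedule,
    choose_sampling_interval,
    generate_replicas,
    heat,
)
from .binding import TitrationSeries, delta_delta_g, fit_ic50
from .dynamics import (
    POST_SA_MINIMIZATION,
    PRE_SA_MINIMIZATION,
    MDState,
    MinimizationSpec,
    minimize_positions,
)
from .forcefield import EnergySystem, ForceFieldParameters
from .structure import ComplexModel, write_ensemble_pdb

__all__ = [
    "SAProtocol",
    "TOY_PROTOCOL",
    "FULL_PROTOCOL",
    "AnnealResult",
    "run_annealing",
    "cluster_ensemble",
    "affinity_table",
    "read_titration_csv",
    "write_run_report",
]


@dataclass
class SAProtocol:
    """All tunables of the simulated-annealing protocol."""

    t0: float = 3000.0
    cooling_factor: float = 0.8
    t_final: float = 300.0
    n_replicas: int = 50
    sampling_interval: float = 2.5  # ps between replica snapshots at t0
    interval_candidates: tuple[float, ...] = ()  # optional auto-selection
    heating_stages: tuple[tuple[float, float], ...] = (
        (1000.0, 10.0), (2000.0, 10.0), (3000.0, 10.0),
    )
    durations: tuple[float, ...] = (10.0, 50.0, 500.0)  # ps per cooling level
    pre_minimization: MinimizationSpec = field(default_factory=lambda: PRE_SA_MINIMIZATION)
    post_minimization: MinimizationSpec = field(default_factory=lambda: POST_SA_MINIMIZATION)
    master_seed: int = 0

    def schedule(self) -> CoolingSchedule:
        return build_schedule(self.t0, self.cooling_factor, self.t_final)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: v for k, v in asdict(self).items()}, sort_keys=True, default=str
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


#: the protocol at its full published scale (hours-days of compute)
FULL_PROTOCOL = SAProtocol()

#: desk-scale protocol used by the synthetic studies and the test suite
TOY_PROTOCOL = SAProtocol(
    n_replicas=8,
    sampling_interval=0.25,
    heating_stages=((1000.0, 0.3), (2000.0, 0.3), (3000.0, 0.3)),
    durations=(0.02, 0.2, 1.0),
)


@dataclass
class AnnealResult:
    """Everything one annealing sweep produces."""

    model: ComplexModel  # minimized starting model
    hot_ensemble: ReplicaEnsemble
    cooled: dict[float, ReplicaEnsemble]  # duration (ps) -> cooled ensemble
    report: dict


def run_annealing(
    model: ComplexModel,
    params: ForceFieldParameters,
    protocol: SAProtocol = TOY_PROTOCOL,
    segment=None,
) -> AnnealResult:
    """Run the full protocol: minimize, heat, sample, cool at each rate.

    Returns the minimized starting model, the 3000 K ensemble and one
    cooled ensemble per requested cooling duration, plus a report dict
    with ensemble statistics per stage (mean ± sd CA-RMSD and energy),
    in the format used by the run reports.
    """
    system = EnergySystem(model, params)
    x0, _ = minimize_positions(system, model.coords, protocol.pre_minimization)
    start = model.copy()
    start.set_coords(x0)
    # re-anchor the positional restraints at the minimized geometry
    start.reference_positions = x0.copy()
    system = EnergySystem(start, params)

    rng = np.random.default_rng(protocol.master_seed)
    state = MDState(x0.copy(), np.zeros_like(x0), system.masses, system.frozen,
                    seed=protocol.master_seed)
    state = heat(state, system, stages=protocol.heating_stages, rng=rng)

    interval = protocol.sampling_interval
    if protocol.interval_candidates:
        interval = choose_sampling_interval(
            list(protocol.interval_candidates), state, system, start,
            master_seed=protocol.master_seed,
        )

    hot = generate_replicas(
        state, system, start, n=protocol.n_replicas, interval=interval,
        master_seed=protocol.master_seed, t_sample=protocol.t0,
    )

    schedule = protocol.schedule()
    cooled = {}
    stats = {"hot": _stats_block(hot, segment)}
    for duration in protocol.durations:
        ens = anneal(hot, system, schedule, duration,
                     post_minimization=protocol.post_minimization, segment=segment)
        cooled[duration] = ens
        stats[f"cooled_{duration}ps"] = _stats_block(ens, segment)

    report = {
        "provenance": {
            "version": __version__,
            "config_hash": protocol.config_hash(),
            "master_seed": protocol.master_seed,
            "sampling_interval_ps": interval,
            "schedule_levels": schedule.temperatures,
        },
        "ensemble_statistics": stats,
    }
    return AnnealResult(model=start, hot_ensemble=hot, cooled=cooled, report=report)


def _stats_block(ensemble: ReplicaEnsemble, segment) -> dict:
    block = {"full": ensemble.statistics()}
    if segment is not None:
        block["segment"] = ensemble.statistics(segment=segment)
    return block


# ---------------------------------------------------------------------
# Clustering stage
# ---------------------------------------------------------------------

def cluster_ensemble(
    ensemble: ReplicaEnsemble,
    segment,
    references=None,
    threshold: float = 2.5,
    joint_config: dict | None = None,
) -> dict:
    """Run both clustering modes on a cooled ensemble and label clusters.

    Returns ``{"nmrclust": ClusterReport, "joint": ClusterReport,
    "rmsd_table": DataFrame}``.  Pairwise clustering uses fixed-frame
    segment CA-RMSD (all replicas share the frozen-scaffold frame); the
    joint mode clusters (RMSD-to-start, final energy).
    """
    model = ensemble.model
    active = ensemble.active()
    seg_cas = [ca_coords(model, r.positions, segment) for r in active]
    start_cas = ca_coords(model, segment=segment)
    energies = np.array([r.energy["total"] for r in active])
    rmsd_to_start = np.array([ca_rmsd(c, start_cas) for c in seg_cas])

    n = len(active)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = ca_rmsd(seg_cas[i], seg_cas[j])

    pair_report = nmrclust(dist)
    _attach_representatives(pair_report, seg_cas, energies)
    joint_report = joint_rmsd_energy_clusters(
        rmsd_to_start, energies, **(joint_config or {})
    )
    _attach_representatives(joint_report, seg_cas, energies)

    if references is not None:
        for report in (pair_report, joint_report):
            rep_cas = [
                seg_cas[report.representatives[ci]]
                if report.representatives[ci] is not None else None
                for ci in range(report.n_clusters)
            ]
            classify_clusters(report, rep_cas, references, threshold=threshold)

    table = pd.DataFrame(
        {
            "replica": [r.index for r in active],
            "rmsd_start_segment": rmsd_to_start,
            "energy_kcal_mol": energies,
        }
    )
    return {"nmrclust": pair_report, "joint": joint_report, "rmsd_table": table}


def _attach_representatives(report, seg_cas, energies) -> None:
    report.representatives = []
    for members in report.clusters:
        coords = np.stack([seg_cas[m] for m in members])
        local = representative(coords, energies=[energies[m] for m in members],
                               ids=members)
        report.representatives.append(members[local])
    # per-cluster mean ± sd RMSD to the cluster representative
    report.rmsd_stats = []
    for ci, members in enumerate(report.clusters):
        rep_ca = seg_cas[report.representatives[ci]]
        values = [ca_rmsd(seg_cas[m], rep_ca) for m in members]
        report.rmsd_stats.append(
            {"to_representative": (float(np.mean(values)), float(np.std(values)))}
        )


# ---------------------------------------------------------------------
# Affinity stage
# ---------------------------------------------------------------------

def read_titration_csv(path) -> list[TitrationSeries]:
    """Load titrations from CSV (peptide, concentration_M, FP_mP, role).

    ``role`` is one of sample / blank / background; the blank and
    background rows supply FP_0 and FP_b for their peptide's series.
    """
    frame = pd.read_csv(path)
    required = {"peptide", "concentration_M", "FP_mP", "role"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"titration CSV missing columns: {sorted(missing)}")
    out = []
    for peptide, group in frame.groupby("peptide", sort=False):
        blanks = group[group["role"] == "blank"]["FP_mP"]
        backgrounds = group[group["role"] == "background"]["FP_mP"]
        if blanks.empty or backgrounds.empty:
            raise ValueError(f"peptide {peptide}: missing blank or background control")
        samples = group[group["role"] == "sample"].sort_values("concentration_M")
        out.append(
            TitrationSeries(
                peptide=str(peptide),
                concentrations=samples["concentration_M"].to_numpy(),
                fp_readings=samples["FP_mP"].to_numpy(),
                fp0=float(blanks.mean()),
                fpb=float(backgrounds.mean()),
            )
        )
    return out


def affinity_table(
    series_list: list[TitrationSeries],
    n_bootstrap: int = 200,
    seed: int = 0,
    ddg: bool = False,
):
    """Fit every titration and tabulate IC50 / ΔG (Table-1 style).

    With ``ddg=True`` also returns the antisymmetric ΔΔG matrix
    (kJ/mol, row vs column; positive = row binds more weakly).
    """
    results = [
        fit_ic50(s, n_bootstrap=n_bootstrap, seed=seed + i)
        for i, s in enumerate(series_list)
    ]
    table = pd.DataFrame(
        {
            "peptide": [r.peptide for r in results],
            "IC50_uM": [r.ic50 * 1e6 for r in results],
            "IC50_CI_low_uM": [r.ic50_ci[0] * 1e6 if r.ic50_ci else np.nan for r in results],
            "IC50_CI_high_uM": [r.ic50_ci[1] * 1e6 if r.ic50_ci else np.nan for r in results],
            "hill": [r.hill for r in results],
            "delta_G_kJ_mol": [r.delta_g for r in results],
        }
    )
    if not ddg:
        return table
    n = len(results)
    matrix = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            matrix[i, j] = delta_delta_g(results[j], results[i])
    ddg_frame = pd.DataFrame(
        matrix, index=table["peptide"], columns=table["peptide"]
    )
    return table, ddg_frame


# ---------------------------------------------------------------------
# Artifact output
# ---------------------------------------------------------------------

def write_run_report(result: AnnealResult, outdir) -> Path:
    """Write ensemble PDBs, per-replica CSVs and the JSON run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ensemble_pdb(result.model, result.hot_ensemble.coordinate_stack(),
                       outdir / "ensemble_hot.pdb")
    for duration, ens in result.cooled.items():
        tag = f"{duration:g}ps"
        write_ensemble_pdb(result.model, ens.coordinate_stack(),
                           outdir / f"ensemble_cooled_{tag}.pdb")
        rows = [
            {
                "replica": r.index,
                "failed": r.failed,
                "energy_kcal_mol": r.energy["total"] if r.energy else np.nan,
                "rmsd_start_full_A": r.rmsd_start_full,
                "rmsd_start_segment_A": r.rmsd_start_segment,
            }
            for r in ens.replicas
        ]
        pd.DataFrame(rows).to_csv(outdir / f"replicas_{tag}.csv", index=False)
    report_path = outdir / "run_report.json"
    report_path.write_text(json.dumps(result.report, indent=2, default=_json_default))
    return report_path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
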