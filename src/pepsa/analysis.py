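"""Conformational analysis of annealed ensembles.

Superposition and CA-RMSD metrics, two clustering modes (pairwise-RMSD
agglomerative clustering with an automatic penalty-based cut, and
density-based clustering of the joint RMSD-energy distribution),
cluster representatives, and conformation-class labels against
reference conformations (extended / helical / beta-turn).

Because the scaffold is frozen during sampling, all replicas of one
complex share its coordinate frame; CA-RMSDs to the starting model are
therefore computed *fixed-frame* by default (no re-superposition).
Comparisons against ideal references, which carry no scaffold frame,
superpose over the compared CA selection instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geometry import kabsch, rmsd as _frame_rmsd
from .pepbuild import ALPHA_HELIX, EXTENDED, TYPE_I_TURN, build_backbone
from .structure import ComplexModel, SpecificitySegment

__all__ = [
    "RMSDRecord",
    "ClusterReport",
    "ReferenceConformation",
    "kabsch_superpose",
    "ca_rmsd",
    "ca_coords",
    "nmrclust",
    "joint_rmsd_energy_clusters",
    "representative",
    "build_references",
    "classify_clusters",
]


@dataclass(frozen=True)
class RMSDRecord:
    replica_id: int
    selection: str  # "full" or "segment"
    reference: str  # "start", "extended", "helix", "beta-turn"
    value: float  # Å

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("RMSD cannot be negative")


@dataclass
class ClusterReport:
    """Cluster memberships over an ensemble of replicas."""

    clusters: list[list[int]]
    fractions: list[float]
    representatives: list[int | None] = field(default_factory=list)
    labels: list[str | None] = field(default_factory=list)
    rmsd_stats: list[dict[str, tuple[float, float]]] = field(default_factory=list)
    noise: list[int] = field(default_factory=list)

    def __post_init__(self):
        total = sum(self.fractions)
        if self.fractions and abs(total - 1.0) > 1e-6:
            raise ValueError("population fractions must sum to 1")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass
class ReferenceConformation:
    label: str
    ca_coords: np.ndarray  # (n_res, 3)
    source: str  # "crystal-pose" | "built-ideal"
    superpose: bool = True  # superpose before RMSD (ideal refs share no frame)


# ---------------------------------------------------------------------
# RMSD machinery
# ---------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rigid superposition; returns (rotation, translation, rmsd)."""
    return kabsch(mobile, reference)


def ca_coords(model: ComplexModel, coords: np.ndarray | None = None,
              segment: SpecificitySegment | str = "full") -> np.ndarray:
    """Extract peptide CA coordinates, optionally restricted to the segment."""
    x = model.coords if coords is None else np.asarray(coords, float)
    if isinstance(segment, SpecificitySegment):
        residues = list(segment.residue_indices)
    else:
        residues = [ri for ri in model.peptide_residues
                    if model.residue_name(ri) not in ("ACE", "NME")]
    idx = []
    for ri in residues:
        try:
            idx.append(model.atom_index(ri, "CA"))
        except KeyError:
            raise ValueError(f"residue {ri} has no CA atom") from None
    return x[idx]


def ca_rmsd(replica_ca: np.ndarray, reference_ca: np.ndarray,
            superpose: bool = False) -> float:
    """CA-RMSD between two equally-sized CA coordinate sets (Å).

    Fixed-frame by default (both structures share the frozen-scaffold
    frame); with ``superpose=True`` an optimal rigid superposition over
    the compared CAs is applied first.
    """
    replica_ca = np.asarray(replica_ca, float)
    reference_ca = np.asarray(reference_ca, float)
    if replica_ca.shape != reference_ca.shape:
        raise ValueError("CA selections differ in size")
    if superpose:
        _, _, value = kabsch(replica_ca, reference_ca)
        return value
    return _frame_rmsd(replica_ca, reference_ca)


# ---------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------

def _cluster_spread(dist: np.ndarray, members: list[int]) -> float:
    if len(members) < 2:
        return 0.0
    sub = dist[np.ix_(members, members)]
    iu = np.triu_indices(len(members), k=1)
    return float(np.mean(sub[iu]))


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo < 1e-12:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def nmrclust(distance_matrix: np.ndarray, allow_singletons: bool = False) -> ClusterReport:
    """Average-linkage clustering with automatic penalty-based cut selection.

    All agglomeration levels of the average-linkage dendrogram are
    scored with ``penalty = minmax(average cluster spread) +
    minmax(cluster count)`` and the level with the smallest penalty is
    returned.  The all-singleton solution is excluded unless
    ``allow_singletons``; ties resolve to fewer clusters.
    """
    dist = np.asarray(distance_matrix, float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(dist)) > 1e-8):
        raise ValueError("distance matrix must have zero diagonal")
    n = dist.shape[0]
    if n == 1:
        return ClusterReport(clusters=[[0]], fractions=[1.0])

    link = linkage(squareform(dist, checks=False), method="average")
    candidate_counts = range(1, n + 1) if allow_singletons else range(1, n)
    levels = []
    for k in candidate_counts:
        flat = fcluster(link, t=k, criterion="maxclust")
        clusters = [list(np.where(flat == c)[0]) for c in np.unique(flat)]
        spread = np.mean([_cluster_spread(dist, m) for m in clusters])
        levels.append((len(clusters), spread, clusters))
    counts = np.array([lv[0] for lv in levels], float)
    spreads = np.array([lv[1] for lv in levels], float)
    penalty = _minmax(spreads) + _minmax(counts)
    best = int(np.lexsort((counts, penalty))[0])
    clusters = sorted(levels[best][2], key=len, reverse=True)
    fractions = [len(m) / n for m in clusters]
    return ClusterReport(clusters=clusters, fractions=fractions)


def joint_rmsd_energy_clusters(
    rmsd_values: np.ndarray,
    energies: np.ndarray,
    neighborhood: float = 0.7,
    min_members: int = 3,
) -> ClusterReport:
    """Density-based grouping of replicas in the standardized (RMSD, energy) plane.

    Both axes are z-scored, making the result invariant to affine
    rescaling of either quantity.  Points in no dense region are
    reported as noise ("other").
    """
    from sklearn.cluster import DBSCAN

    r = np.asarray(rmsd_values, float)
    e = np.asarray(energies, float)
    if r.shape != e.shape:
        raise ValueError("rmsd and energy lists differ in length")
    n = len(r)
    if n < min_members:
        warnings.warn("fewer points than min_members: single-cluster fallback",
                      stacklevel=2)
        return ClusterReport(clusters=[list(range(n))], fractions=[1.0])

    def _z(v):
        sd = np.std(v)
        return (v - np.mean(v)) / sd if sd > 1e-12 else np.zeros_like(v)

    points = np.column_stack([_z(r), _z(e)])
    labels = DBSCAN(eps=neighborhood, min_samples=min_members).fit_predict(points)
    clusters = [list(np.where(labels == c)[0]) for c in np.unique(labels) if c >= 0]
    clusters.sort(key=len, reverse=True)
    noise = list(np.where(labels < 0)[0])
    if not clusters:
        warnings.warn("no dense region found: single-cluster fallback", stacklevel=2)
        return ClusterReport(clusters=[list(range(n))], fractions=[1.0])
    assigned = sum(len(m) for m in clusters) + len(noise)
    assert assigned == n
    fractions = [len(m) / n for m in clusters] + ([len(noise) / n] if noise else [])
    report = ClusterReport(
        clusters=clusters + ([noise] if noise else []),
        fractions=fractions,
        noise=noise,
    )
    report.labels = [None] * len(clusters) + (["other"] if noise else [])
    return report


def representative(member_coords: np.ndarray, energies=None, ids=None) -> int:
    """Index of the member closest to the coordinate-wise mean structure.

    Ties (within 1e-9 Å) break to the lowest energy, then the lowest id.
    """
    coords = np.asarray(member_coords, float)
    if coords.ndim != 3 or len(coords) == 0:
        raise ValueError("need (n_members, n_atoms, 3) coordinates")
    n = len(coords)
    mean_structure = coords.mean(axis=0)
    dists = np.array([_frame_rmsd(c, mean_structure) for c in coords])
    best = float(np.min(dists))
    tied = np.where(dists <= best + 1e-9)[0]
    if len(tied) > 1 and energies is not None:
        e = np.asarray(energies, float)[tied]
        tied = tied[np.where(e <= e.min() + 1e-12)[0]]
    if ids is not None:
        tied = sorted(tied, key=lambda i: ids[i])
    return int(tied[0])


# ---------------------------------------------------------------------
# Reference conformations and classification
# ---------------------------------------------------------------------

def build_references(
    n_residues: int,
    extended_pose: np.ndarray | None = None,
    helix_phi_psi: tuple[float, float] = ALPHA_HELIX,
    turn_pose: np.ndarray | None = None,
) -> list[ReferenceConformation]:
    """Extended, ideal-helix and beta-turn CA references for a peptide segment.

    ``extended_pose`` / ``turn_pose`` may supply crystal-pose CA
    coordinates (fixed-frame comparison); otherwise ideal geometries are
    built: extended at (phi, psi) = (-120°, 120°), helix at (-57°, -47°)
    and a type-I turn on the central residues.
    """
    refs = []
    if extended_pose is not None:
        refs.append(ReferenceConformation("extended", np.asarray(extended_pose, float),
                                          "crystal-pose", superpose=False))
    else:
        bb = build_backbone([EXTENDED] * n_residues)
        refs.append(ReferenceConformation(
            "extended", np.array([r["CA"] for r in bb]), "built-ideal"))

    bb = build_backbone([helix_phi_psi] * n_residues)
    refs.append(ReferenceConformation(
        "helical", np.array([r["CA"] for r in bb]), "built-ideal"))

    if turn_pose is not None:
        refs.append(ReferenceConformation("beta-turn", np.asarray(turn_pose, float),
                                          "crystal-pose", superpose=False))
    else:
        if n_residues < 4:
            phi_psi = [EXTENDED] + [TYPE_I_TURN[0], TYPE_I_TURN[1]][: n_residues - 1]
        else:
            pad = n_residues - 3
            phi_psi = [EXTENDED] + list(TYPE_I_TURN) + [EXTENDED] * pad
        bb = build_backbone(phi_psi)
        refs.append(ReferenceConformation(
            "beta-turn", np.array([r["CA"] for r in bb]), "built-ideal"))
    return refs


def classify_clusters(
    report: ClusterReport,
    representative_cas: list[np.ndarray],
    references: list[ReferenceConformation],
    threshold: float = 2.5,
) -> ClusterReport:
    """Label clusters by their representative's proximity to a reference.

    A cluster gets the label of the nearest reference if the segment
    CA-RMSD is within ``threshold`` (Å); otherwise "other".  Clusters
    already labeled (e.g. density-clustering noise) are left alone.
    """
    labels = list(report.labels) if report.labels else [None] * report.n_clusters
    for ci, cas in enumerate(representative_cas):
        if ci >= len(labels):
            labels.append(None)
        if labels[ci] is not None or cas is None:
            continue
        best_label, best_value = "other", np.inf
        for ref in references:
            if len(ref.ca_coords) != len(cas):
                continue
            value = ca_rmsd(cas, ref.ca_coords, superpose=ref.superpose)
            if value < best_value:
                best_label, best_value = ref.label, value
        labels[ci] = best_label if best_value <= threshold else "other"
    report.labels = labels
    return report
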