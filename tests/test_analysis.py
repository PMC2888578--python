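"""RMSD metrics, clustering, representatives, conformation labels."""

import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from pepsa.analysis import (
    ReferenceConformation,
    build_references,
    ca_rmsd,
    classify_clusters,
    joint_rmsd_energy_clusters,
    nmrclust,
    representative,
)
from pepsa.geometry import dihedral_angle
from pepsa.pepbuild import build_backbone


def brute_force_nmrclust(dist):
    """Independent re-derivation: enumerate every agglomeration level of the
    average-linkage dendrogram and score it with the same penalty."""
    n = dist.shape[0]
    link = linkage(squareform(dist, checks=False), method="average")
    levels = []
    for k in range(1, n):  # singleton-only solution excluded
        flat = fcluster(link, t=k, criterion="maxclust")
        clusters = [sorted(np.where(flat == c)[0]) for c in np.unique(flat)]
        spreads = []
        for members in clusters:
            if len(members) < 2:
                spreads.append(0.0)
            else:
                pairs = list(itertools.combinations(members, 2))
                spreads.append(np.mean([dist[i, j] for i, j in pairs]))
        levels.append((len(clusters), float(np.mean(spreads)), clusters))
    counts = np.array([l[0] for l in levels], float)
    spreads = np.array([l[1] for l in levels], float)

    def norm(v):
        span = np.ptp(v)
        return np.zeros_like(v) if span < 1e-12 else (v - v.min()) / span

    penalty = norm(spreads) + norm(counts)
    best = min(range(len(levels)), key=lambda i: (penalty[i], counts[i]))
    return sorted([tuple(c) for c in levels[best][2]], key=len, reverse=True)


class TestCaRmsd:
    def test_identity_zero(self, rng):
        x = rng.normal(size=(5, 3))
        assert ca_rmsd(x, x) == 0.0

    def test_uniform_translation_fixed_frame(self, rng):
        x = rng.normal(size=(4, 3))
        shifted = x + np.array([0.0, 0.0, 2.0])
        assert ca_rmsd(shifted, x) == pytest.approx(2.0)
        assert ca_rmsd(shifted, x, superpose=True) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_three_residue_case(self):
        a = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        b = np.array([[0.0, 0, 1], [1.0, 0, 0], [2.0, 2, 0]])
        # direct arithmetic: sqrt(mean(1^2 + 0 + 2^2))
        assert ca_rmsd(a, b) == pytest.approx(np.sqrt((1 + 0 + 4) / 3))

    @pytest.mark.parametrize("seed", range(5))
    def test_pseudometric_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(size=(3, 6, 3)) * 3
        dxy, dyz, dxz = ca_rmsd(x, y), ca_rmsd(y, z), ca_rmsd(x, z)
        assert dxy == pytest.approx(ca_rmsd(y, x))
        assert dxz <= dxy + dyz + 1e-12


class TestNmrclust:
    def test_all_identical_single_cluster(self):
        report = nmrclust(np.zeros((5, 5)))
        assert report.n_clusters == 1
        assert report.fractions == [1.0]

    def test_two_tight_triads(self, rng):
        pts = np.concatenate([rng.normal(scale=0.1, size=(3, 2)),
                              rng.normal(scale=0.1, size=(3, 2)) + 10.0])
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        report = nmrclust(dist)
        assert report.n_clusters == 2
        assert sorted(len(c) for c in report.clusters) == [3, 3]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(6, 2)) * rng.uniform(0.5, 3)
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        report = nmrclust(dist)
        got = sorted([tuple(sorted(c)) for c in report.clusters], key=len,
                     reverse=True)
        assert got == brute_force_nmrclust(dist)

    def test_invariant_to_ordering_and_scale(self, rng):
        pts = np.concatenate([rng.normal(scale=0.2, size=(4, 2)),
                              rng.normal(scale=0.2, size=(4, 2)) + 5.0])
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        base = nmrclust(dist)
        scaled = nmrclust(dist * 7.5)
        assert [sorted(c) for c in base.clusters] == [sorted(c) for c in scaled.clusters]
        perm = rng.permutation(8)
        permuted = nmrclust(dist[np.ix_(perm, perm)])
        base_sets = {frozenset(c) for c in base.clusters}
        permuted_sets = {frozenset(perm[list(c)]) for c in permuted.clusters}
        assert base_sets == permuted_sets

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            nmrclust(bad)

    def test_fractions_sum_to_one(self, rng):
        pts = rng.normal(size=(9, 2))
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        report = nmrclust(dist)
        assert sum(report.fractions) == pytest.approx(1.0)


class TestJointClusters:
    def test_two_separated_blobs(self, rng):
        r = np.concatenate([rng.normal(1.0, 0.1, 20), rng.normal(1.0, 0.1, 20)])
        e = np.concatenate([rng.normal(-100, 0.5, 20), rng.normal(-50, 0.5, 20)])
        report = joint_rmsd_energy_clusters(r, e)
        assert report.n_clusters - (1 if report.noise else 0) == 2

    def test_all_identical_single_cluster(self):
        report = joint_rmsd_energy_clusters(np.ones(10), np.full(10, -5.0))
        assert report.n_clusters == 1

    def test_energy_axis_affine_invariance(self, rng):
        r = np.concatenate([rng.normal(1, 0.1, 15), rng.normal(4, 0.1, 15)])
        e = np.concatenate([rng.normal(-100, 1, 15), rng.normal(-60, 1, 15)])
        a = joint_rmsd_energy_clusters(r, e)
        b = joint_rmsd_energy_clusters(r, e * 4.184 + 1000.0)
        assert [sorted(c) for c in a.clusters] == [sorted(c) for c in b.clusters]

    def test_fallback_below_min_members(self):
        with pytest.warns(UserWarning, match="fallback"):
            report = joint_rmsd_energy_clusters(np.array([1.0, 2.0]),
                                                np.array([0.0, 1.0]))
        assert report.n_clusters == 1


class TestRepresentative:
    def test_singleton(self):
        assert representative(np.zeros((1, 4, 3))) == 0

    def test_symmetric_pair_tie_broken_by_energy(self):
        mean = np.zeros((3, 3))
        a = mean + np.array([1.0, 0, 0])
        b = mean - np.array([1.0, 0, 0])
        assert representative(np.stack([a, b]), energies=[5.0, 2.0]) == 1
        assert representative(np.stack([a, b]), energies=[2.0, 5.0]) == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_argmin(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(5, 6, 3))
        mean = coords.mean(axis=0)
        dists = [np.sqrt(np.mean(np.sum((c - mean) ** 2, axis=1))) for c in coords]
        assert representative(coords) == int(np.argmin(dists))


class TestReferences:
    def test_helix_dihedrals_recovered(self):
        bb = build_backbone([(-57.0, -47.0)] * 5)
        for i in range(1, 4):
            phi = dihedral_angle(bb[i - 1]["C"], bb[i]["N"], bb[i]["CA"], bb[i]["C"])
            psi = dihedral_angle(bb[i]["N"], bb[i]["CA"], bb[i]["C"], bb[i + 1]["N"])
            assert np.rad2deg(phi) == pytest.approx(-57.0, abs=0.1)
            assert np.rad2deg(psi) == pytest.approx(-47.0, abs=0.1)

    def test_extended_longer_than_helix(self):
        refs = {r.label: r for r in build_references(6)}
        ext = refs["extended"].ca_coords
        hel = refs["helical"].ca_coords
        assert (np.linalg.norm(ext[-1] - ext[0])
                > np.linalg.norm(hel[-1] - hel[0]))

    def test_turn_ca_distance_criterion(self):
        refs = {r.label: r for r in build_references(4)}
        turn = refs["beta-turn"].ca_coords
        assert np.linalg.norm(turn[3] - turn[0]) < 7.0

    def test_supplied_pose_used_verbatim(self, rng):
        pose = rng.normal(size=(4, 3))
        refs = {r.label: r for r in build_references(4, extended_pose=pose)}
        np.testing.assert_array_equal(refs["extended"].ca_coords, pose)
        assert refs["extended"].source == "crystal-pose"
        assert ca_rmsd(pose, refs["extended"].ca_coords) == 0.0


class TestClassification:
    @staticmethod
    def _report_with(cas):
        from pepsa.analysis import ClusterReport

        return ClusterReport(clusters=[[0]], fractions=[1.0],
                             representatives=[0]), [cas]

    def test_exact_match_labeled(self):
        refs = build_references(4)
        report, cas = self._report_with(refs[0].ca_coords.copy())
        out = classify_clusters(report, cas, refs)
        assert out.labels == ["extended"]

    def test_far_from_everything_is_other(self, rng):
        refs = build_references(4)
        report, cas = self._report_with(rng.normal(size=(4, 3)) * 50)
        out = classify_clusters(report, cas, refs)
        assert out.labels == ["other"]

    @pytest.mark.parametrize("offset,expected", [(2.4, "extended"), (2.6, "other")])
    def test_threshold_boundary(self, offset, expected):
        # a pose exactly `offset` Å (fixed-frame) from the extended reference
        ref_pose = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0], [11.4, 0, 0]])
        refs = [ReferenceConformation("extended", ref_pose, "crystal-pose",
                                      superpose=False)]
        shifted = ref_pose + np.array([0.0, 0.0, offset])
        report, cas = self._report_with(shifted)
        out = classify_clusters(report, cas, refs, threshold=2.5)
        assert out.labels == [expected]
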