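"""Low-level rigid-body and internal-coordinate geometry.

Everything operates on plain ``(N, 3)`` float arrays in Ångström. The
higher-level modules (structure building, RMSD analysis) wrap these
primitives; they are exposed here because the test-suite also uses them
as independent building blocks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "kabsch",
    "apply_transform",
    "rmsd",
    "dihedral_angle",
    "bond_angle",
    "place_atom",
]


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` is the superposed copy.  The
    rotation is always proper (determinant +1); reflections are rejected
    by flipping the sign of the smallest singular vector pair.

    Raises
    ------
    ValueError
        If the two selections differ in size, contain fewer than three
        points, or are too degenerate (collinear) to define a frame.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"selection size mismatch: {mobile.shape} vs {reference.shape}"
        )
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")

    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    x = mobile - mob_center
    y = reference - ref_center

    cov = x.T @ y
    u, s, vt = np.linalg.svd(cov)
    # Collinear point sets leave the rotation about the line undetermined.
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) selection: superposition ill-conditioned")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rotation = vt.T @ flip @ u.T
    translation = ref_center - rotation @ mob_center

    moved = x @ rotation.T
    value = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return rotation, translation, value


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply a ``kabsch`` result to an arbitrary coordinate set."""
    return np.asarray(coords, dtype=float) @ np.asarray(rotation).T + translation


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain fixed-frame RMSD between two equally-sized coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in radians."""
    u = np.asarray(a, float) - b
    v = np.asarray(c, float) - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in radians, IUPAC sign convention."""
    b0 = np.asarray(p1, float) - p0
    b1 = np.asarray(p2, float) - p1
    b2 = np.asarray(p3, float) - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def place_atom(a, b, c, bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Place atom ``d`` from internal coordinates relative to ``a-b-c``.

    ``bond`` is the c-d distance (Å), ``angle`` the b-c-d angle and
    ``dihedral`` the a-b-c-d torsion, both in radians.  This is the NeRF
    (natural extension reference frame) construction used to grow capped
    termini, mutant side chains and ideal reference backbones.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    norm_n = np.linalg.norm(n)
    if norm_n < 1e-12:
        raise ValueError("collinear reference atoms for internal-coordinate placement")
    n /= norm_n
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            -bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local
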