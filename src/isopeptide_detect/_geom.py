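"""Low-level 3D geometry primitives shared across modules.

All angles are in degrees; all lengths in Angstrom.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle of the chain p0-p1-p2-p3 in degrees, in (-180, 180].

    Uses the projection formulation: the angle between p0->p1 and p2->p3
    measured around the p1->p2 axis, with IUPAC sign convention (clockwise
    positive when looking from p1 to p2).
    """
    b0 = np.asarray(p0, dtype=float) - np.asarray(p1, dtype=float)
    b1 = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    b2 = np.asarray(p3, dtype=float) - np.asarray(p2, dtype=float)
    b1n = b1 / np.linalg.norm(b1)
    # projections of b0, b2 onto the plane normal to b1
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    bond_angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom D bonded to C with |CD| = bond_length, angle(B,C,D) =
    bond_angle and dihedral(A,B,C,D) = torsion (natural extension reference
    frame construction)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond_length * np.cos(theta),
            bond_length * np.sin(theta) * np.cos(chi),
            bond_length * np.sin(theta) * np.sin(chi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD between two (n, 3) coordinate sets after optimal rigid-body
    superposition (translation + proper rotation)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("coordinate sets must both have shape (n, 3)")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    _, rssd = Rotation.align_vectors(pc, qc)
    return float(rssd / np.sqrt(p.shape[0]))


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation matrix and a translation vector."""
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-50.0, 50.0, size=3)
    return rot, trans


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-spiral lattice).

    Deterministic, so downstream surface areas are bit-reproducible.
    """
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))
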