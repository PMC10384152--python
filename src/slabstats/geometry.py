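"""Torsion angles, rotations and internal-coordinate atom placement."""

from __future__ import annotations

import numpy as np

from .exceptions import GeometryError

_EPS = 1e-12


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < _EPS):
        raise GeometryError(f"zero-length {what}")
    return v / n


def dihedral_angle(p1, p2, p3, p4) -> float:
    """IUPAC torsion angle of four points, in degrees on [0, 360).

    cis (eclipsed, p1 and p4 on the same side) is 0°, anti/trans is 180°.
    The value is invariant under rigid rotation and translation of all four
    points. Raises :class:`GeometryError` if any bonded pair coincides or a
    middle triple is collinear.
    """
    return float(dihedral_angles(p1, p2, p3, p4))


def dihedral_angles(p1, p2, p3, p4) -> np.ndarray:
    """Vectorized :func:`dihedral_angle`; inputs broadcast as (..., 3)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.any(np.linalg.norm(b, axis=-1) < _EPS):
            raise GeometryError("consecutive torsion points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-10) or np.any(
        np.linalg.norm(n2, axis=-1) < 1e-10
    ):
        raise GeometryError("collinear triple in torsion")
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2u, axis=-1)
    phi = np.degrees(np.arctan2(y, x))
    return np.mod(phi, 360.0)


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, [0, 180]."""
    u = _unit(np.asarray(u, dtype=float))
    v = _unit(np.asarray(v, dtype=float))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg``."""
    k = _unit(np.asarray(axis, dtype=float), "rotation axis").ravel()
    a = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def rotation_aligning(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit direction of ``u`` onto that of ``v``."""
    u = _unit(np.asarray(u, dtype=float)).ravel()
    v = _unit(np.asarray(v, dtype=float)).ravel()
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180° flip about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, 180.0)
    axis = np.cross(u, v)
    angle = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return rotation_about_axis(axis, angle)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d from internal coordinates relative to chain a-b-c.

    The result satisfies |cd| = bond, angle(b, c, d) = angle_deg and
    dihedral(a, b, c, d) = torsion_deg under the convention of
    :func:`dihedral_angle`.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    bc = _unit(c - b, "b-c bond")
    n = np.cross(b - a, bc)
    if np.linalg.norm(n) < 1e-10:
        raise GeometryError("collinear a-b-c reference for atom placement")
    n = _unit(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
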