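"""Small 3D geometry helpers shared by the annotation and phantom modules."""

from __future__ import annotations

import numpy as np


def normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, normalize(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else float(ang)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given a-b-c, |c-d|, angle(b,c,d) and torsion(a,b,c,d).

    Natural-extension-of-reference-frame construction used to build ideal
    backbones from internal coordinates.
    """
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = normalize(c - b)
    n = normalize(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        -bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_from_axis_angle(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = normalize(np.asarray(axis, dtype=np.float64))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)
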