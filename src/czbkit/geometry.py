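"""Small geometric primitives: internal-coordinate atom placement and rotations.

Everything works on plain ``(3,)`` / ``(n, 3)`` float64 arrays in Å.
"""

from __future__ import annotations

import numpy as np


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    v1 = np.asarray(p0, float) - np.asarray(p1, float)
    v2 = np.asarray(p2, float) - np.asarray(p1, float)
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom D from internal coordinates (NeRF construction).

    D is bonded to ``c`` with bond length ``bond`` (Å), angle(b, c, D) =
    ``angle`` (degrees) and dihedral(a, b, c, D) = ``torsion`` (degrees).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    # local displacement in the frame where bc defines x
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # collinear reference frame: pick an arbitrary perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """3x3 rotation matrix about a (normalised internally) axis, degrees."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    x, y, z = axis
    return np.array(
        [
            [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
            [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
            [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)],
        ]
    )


def rotate_about_line(
    coords: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_deg: float
) -> np.ndarray:
    """Rotate points about the line through ``origin`` along ``axis``."""
    rot = rotation_about_axis(axis, angle_deg)
    return (np.asarray(coords, float) - origin) @ rot.T + origin


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` nearly uniform unit-sphere points (golden-section spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
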