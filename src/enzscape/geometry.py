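"""Internal-coordinate geometry: bonds, angles, dihedrals and their gradients.

All functions are vectorized over consecutive tuples of a single chain:
bonds over pairs ``(i, i+1)``, angles over triples ``(i, i+1, i+2)`` and
dihedrals over quadruples ``(i, .., i+3)``.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "bond_lengths",
    "bond_angles",
    "dihedral_angles",
    "angle_gradients",
    "dihedral_gradients",
    "wrap_angle",
]

_EPS = 1e-12


def bond_lengths(coords: np.ndarray) -> np.ndarray:
    """Consecutive Calpha-Calpha distances, shape (n-1,)."""
    d = np.diff(coords, axis=0)
    return np.linalg.norm(d, axis=1)


def bond_angles(coords: np.ndarray) -> np.ndarray:
    """Angles (rad) at each interior bead of consecutive triples, shape (n-2,)."""
    a, b, c = coords[:-2], coords[1:-1], coords[2:]
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    h = np.einsum("ij,ij->i", u, v) / np.maximum(nu * nv, _EPS)
    return np.arccos(np.clip(h, -1.0, 1.0))


def dihedral_angles(coords: np.ndarray) -> np.ndarray:
    """Dihedral angles (rad, in (-pi, pi]) of consecutive quadruples, shape (n-3,)."""
    p0, p1, p2, p3 = coords[:-3], coords[1:-2], coords[2:-1], coords[3:]
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.maximum(np.linalg.norm(b2, axis=1), _EPS)[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    return np.arctan2(y, x)


def wrap_angle(delta: np.ndarray | float) -> np.ndarray | float:
    """Wrap an angle difference into (-pi, pi]."""
    return -np.mod(-np.asarray(delta) + np.pi, 2.0 * np.pi) + np.pi


def angle_gradients(coords: np.ndarray):
    """Angles and gradients d(theta)/d(a,b,c).

    Returns ``(theta, ga, gb, gc)`` with each gradient of shape (n-2, 3).
    """
    a, b, c = coords[:-2], coords[1:-1], coords[2:]
    u = a - b
    v = c - b
    nu = np.maximum(np.linalg.norm(u, axis=1), _EPS)
    nv = np.maximum(np.linalg.norm(v, axis=1), _EPS)
    h = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(h)
    # the 0.05 floor caps the geometric gradient near collinear triples
    s = np.maximum(np.sqrt(1.0 - h * h), 0.05)
    inv = -1.0 / s
    ga = inv[:, None] * (v / (nu * nv)[:, None] - (h / nu**2)[:, None] * u)
    gc = inv[:, None] * (u / (nu * nv)[:, None] - (h / nv**2)[:, None] * v)
    gb = -ga - gc
    return theta, ga, gb, gc


def dihedral_gradients(coords: np.ndarray):
    """Dihedrals and gradients d(phi)/d(p0..p3) (Blondel-Karplus form).

    Returns ``(phi, g0, g1, g2, g3)`` with each gradient of shape (n-3, 3).
    """
    p0, p1, p2, p3 = coords[:-3], coords[1:-2], coords[2:-1], coords[3:]
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.maximum(np.linalg.norm(b2, axis=1), _EPS)
    m = np.cross(n1, b2 / nb2[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m, n2)
    phi = np.arctan2(y, x)

    # the floor caps the dihedral gradient near collinear triples
    n1sq = np.maximum(np.einsum("ij,ij->i", n1, n1), 2.0)
    n2sq = np.maximum(np.einsum("ij,ij->i", n2, n2), 2.0)
    g0 = (nb2 / n1sq)[:, None] * n1
    g3 = -(nb2 / n2sq)[:, None] * n2
    d12 = np.einsum("ij,ij->i", b1, b2) / nb2**2
    d32 = np.einsum("ij,ij->i", b3, b2) / nb2**2
    g1 = -(1.0 + d12)[:, None] * g0 + d32[:, None] * g3
    g2 = d12[:, None] * g0 - (1.0 + d32)[:, None] * g3
    return phi, g0, g1, g2, g3
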