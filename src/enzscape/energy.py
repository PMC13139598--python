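"""Single-basin structure-based potential (reference implementation).

The potential of one reference conformation comprises:

* harmonic bonds              ``V_bond = sum_i k_b (b_i - b_i^0)^2``
* Gaussian angle restraints   ``V_angle = -eps_a sum exp(-(th - th0)^2 / 2 w_th^2)``
* Gaussian dihedral restraints (difference wrapped to (-pi, pi])
* a weak flexible-local prior: broader, shallow Gaussians on the same
  angles/dihedrals (width doubled, strength ``eps_flp``) standing in for
  sequence-dependent chain flexibility
* Gaussian native-contact attractions
* repulsive excluded volume ``eps (sigma/r)^12`` between non-bonded,
  non-contact pairs more than four residues apart, truncated and shifted
  to zero at ``r = 2.5 sigma``

This module is the clear, vectorized NumPy path used for model building and
verification; the simulation engine evaluates the same functional forms in
a compiled kernel (see ``_kernels``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .structure import ContactSet, ReferenceConformation

__all__ = [
    "SingleBasinParams",
    "bonded_energy",
    "contact_energy",
    "excluded_volume_energy",
    "single_basin_energy",
    "exv_candidate_pairs",
]


@dataclass
class SingleBasinParams:
    """Strengths (kcal/mol, widths in rad/A) of the single-basin terms."""

    k_bond: float = 100.0  # kcal/mol/A^2
    eps_angle: float = 1.0
    eps_dihedral: float = 1.0
    eps_flp: float = 0.1
    eps_contact: float = 0.5
    w_theta: float = 0.15  # rad
    w_phi: float = 0.3  # rad
    w_c: float = 2.5  # A
    eps_exv: float = 1.0
    sigma_exv: float = 4.0  # A
    exv_cutoff_factor: float = 2.5

    def __post_init__(self) -> None:
        for name in ("k_bond", "eps_angle", "eps_dihedral", "eps_flp", "eps_contact", "eps_exv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("w_theta", "w_phi", "w_c", "sigma_exv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _gaussian_well(delta: np.ndarray, eps: float, width: float):
    """-eps * exp(-delta^2 / (2 w^2)) and its derivative wrt delta."""
    g = np.exp(-(delta**2) / (2.0 * width**2))
    e = -eps * g
    de = eps * g * delta / width**2
    return e, de


def bonded_energy(
    coords: np.ndarray,
    ref: ReferenceConformation,
    p: SingleBasinParams,
):
    """Local terms (bonds, angles, dihedrals, flexible prior) and gradient."""
    coords = np.asarray(coords, dtype=np.float64)
    if len(coords) != ref.n_residues:
        raise ValueError("coordinate array does not match the reference chain length")
    n = len(coords)
    grad = np.zeros_like(coords)
    energy = 0.0

    # bonds
    d = np.diff(coords, axis=0)
    b = np.linalg.norm(d, axis=1)
    db = b - ref.b0
    energy += float(p.k_bond * np.sum(db**2))
    f = (2.0 * p.k_bond * db / np.maximum(b, 1e-12))[:, None] * d
    np.add.at(grad, np.arange(n - 1), -f)
    np.add.at(grad, np.arange(1, n), f)

    # angles (native Gaussian + flexible prior at doubled width)
    if n >= 3:
        theta, ga, gb, gc = geometry.angle_gradients(coords)
        dth = theta - ref.theta0
        for eps, w in ((p.eps_angle, p.w_theta), (p.eps_flp, 2.0 * p.w_theta)):
            if eps == 0.0:
                continue
            e, de = _gaussian_well(dth, eps, w)
            energy += float(np.sum(e))
            np.add.at(grad, np.arange(n - 2), de[:, None] * ga)
            np.add.at(grad, np.arange(1, n - 1), de[:, None] * gb)
            np.add.at(grad, np.arange(2, n), de[:, None] * gc)

    # dihedrals
    if n >= 4:
        phi, g0, g1, g2, g3 = geometry.dihedral_gradients(coords)
        dph = geometry.wrap_angle(phi - ref.phi0)
        for eps, w in ((p.eps_dihedral, p.w_phi), (p.eps_flp, 2.0 * p.w_phi)):
            if eps == 0.0:
                continue
            e, de = _gaussian_well(dph, eps, w)
            energy += float(np.sum(e))
            np.add.at(grad, np.arange(n - 3), de[:, None] * g0)
            np.add.at(grad, np.arange(1, n - 2), de[:, None] * g1)
            np.add.at(grad, np.arange(2, n - 1), de[:, None] * g2)
            np.add.at(grad, np.arange(3, n), de[:, None] * g3)

    return energy, grad


def contact_energy(coords: np.ndarray, contacts: ContactSet, p: SingleBasinParams):
    """Gaussian native-contact attraction and gradient."""
    coords = np.asarray(coords, dtype=np.float64)
    grad = np.zeros_like(coords)
    if len(contacts) == 0:
        return 0.0, grad
    i = contacts.pairs[:, 0] - 1
    j = contacts.pairs[:, 1] - 1
    d = coords[j] - coords[i]
    r = np.linalg.norm(d, axis=1)
    dr = r - contacts.r0
    g = np.exp(-(dr**2) / (2.0 * p.w_c**2))
    energy = float(np.sum(-contacts.eps * g))
    de = contacts.eps * g * dr / p.w_c**2  # dV/dr
    f = (de / np.maximum(r, 1e-12))[:, None] * d
    np.add.at(grad, i, -f)
    np.add.at(grad, j, f)
    return energy, grad


def exv_candidate_pairs(
    n: int,
    exclusions: "set[tuple[int, int]] | np.ndarray",
    min_seq_sep: int = 4,
) -> np.ndarray:
    """(m, 2) array of 0-based pairs subject to excluded volume.

    ``exclusions`` holds 1-based (I, J) contact pairs (I < J); bonded
    neighbours up to ``min_seq_sep`` are excluded by the sequence rule.
    """
    if isinstance(exclusions, np.ndarray):
        excl = {(int(a), int(b)) for a, b in exclusions}
    else:
        excl = {(min(a, b), max(a, b)) for a, b in exclusions}
    ii, jj = np.triu_indices(n, k=min_seq_sep + 1)
    keep = np.array([(int(a) + 1, int(b) + 1) not in excl for a, b in zip(ii, jj)])
    if len(keep) == 0:
        return np.empty((0, 2), dtype=np.int64)
    return np.stack([ii[keep], jj[keep]], axis=1).astype(np.int64)


def excluded_volume_energy(
    coords: np.ndarray,
    pairs: np.ndarray,
    p: SingleBasinParams,
):
    """Truncated-and-shifted ``eps (sigma/r)^12`` repulsion over given 0-based pairs."""
    coords = np.asarray(coords, dtype=np.float64)
    grad = np.zeros_like(coords)
    if len(pairs) == 0:
        return 0.0, grad
    i, j = pairs[:, 0], pairs[:, 1]
    d = coords[j] - coords[i]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-9):
        raise ValueError("overlapping beads (r = 0) in excluded-volume pair")
    rc = p.exv_cutoff_factor * p.sigma_exv
    shift = p.eps_exv * (1.0 / p.exv_cutoff_factor) ** 12
    mask = r < rc
    if not np.any(mask):
        return 0.0, grad
    rm = r[mask]
    e = p.eps_exv * (p.sigma_exv / rm) ** 12
    energy = float(np.sum(e - shift))
    de = -12.0 * e / rm  # dV/dr
    f = np.zeros((len(r),))
    f[mask] = de
    fv = (f / np.maximum(r, 1e-12))[:, None] * d
    np.add.at(grad, i, -fv)
    np.add.at(grad, j, fv)
    return energy, grad


def single_basin_energy(
    coords: np.ndarray,
    ref: ReferenceConformation,
    p: SingleBasinParams,
    exv_pairs: np.ndarray | None = None,
):
    """Full Eq.-style single-basin potential; gradient included.

    Excluded volume is evaluated only when candidate pairs are supplied
    (the multi-basin composition owns a single global repulsion term).
    """
    e1, g1 = bonded_energy(coords, ref, p)
    e2, g2 = contact_energy(coords, ref.contacts, p)
    energy, grad = e1 + e2, g1 + g2
    if exv_pairs is not None:
        e3, g3 = excluded_volume_energy(coords, exv_pairs, p)
        energy += e3
        grad += g3
    return energy, grad
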