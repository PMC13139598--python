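"""Kinetic Monte Carlo chemical step.

Phosphoryl transfer is represented as an instantaneous occupancy change
(substrate, substrate) -> (product, product), fired with probability
``1 - exp(-k_f dt)`` per attempt, and the reverse with ``k_r``. Chemistry is
gated on the catalytically competent state: the enzyme must be classified
closed, both pockets must hold the right species, and the pocket contacts
must be formed (preorganized active site).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ligand import BindingSite, LigandOccupancy
from .multibasin import MultiBasinModel, classify_conformation

__all__ = ["ChemistryParams", "is_competent", "contact_fraction", "kmc_reaction_step"]


@dataclass
class ChemistryParams:
    """Forward/reverse catalytic rates (per mapped ms) and the gate."""

    k_f: float = 500.0
    k_r: float = 40.0
    q_min: float = 0.6  # min fraction of pocket pairs within 1.5 sigma of holo

    def __post_init__(self) -> None:
        if self.k_f < 0 or self.k_r < 0:
            raise ValueError("rates must be non-negative")
        if not (0.0 < self.q_min <= 1.0):
            raise ValueError("q_min must be in (0, 1]")


def contact_fraction(coords: np.ndarray, site: BindingSite, species: str) -> float:
    """Fraction of pocket pairs within 1.5 sigma of their holo distance."""
    i = site.pairs[:, 0] - 1
    j = site.pairs[:, 1] - 1
    r = np.linalg.norm(coords[j] - coords[i], axis=1)
    formed = np.abs(r - site.r0(species)) <= 1.5 * site.sigma
    return float(formed.mean())


def is_competent(
    coords: np.ndarray,
    occupancy: LigandOccupancy,
    model: MultiBasinModel,
    sites: list[BindingSite],
    direction: str,
    q_min: float = 0.6,
) -> bool:
    """True iff the chemical step may fire in the given direction."""
    if direction == "forward":
        required = ("substrate", "substrate")
    elif direction == "reverse":
        required = ("product", "product")
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if occupancy.species != required:
        return False
    if classify_conformation(coords, model) != "closed":
        return False
    for site, species in zip(sites, occupancy.species):
        if contact_fraction(coords, site, species) < q_min:
            return False
    return True


def kmc_reaction_step(
    coords: np.ndarray,
    occupancy: LigandOccupancy,
    model: MultiBasinModel,
    sites: list[BindingSite],
    params: ChemistryParams,
    dt_ms: float,
    rng: np.random.Generator,
    log=None,
    step: int = 0,
    time_ms: float = 0.0,
):
    """One kMC attempt; forward and reverse are mutually exclusive per call."""
    if is_competent(coords, occupancy, model, sites, "forward", params.q_min):
        if params.k_f > 0 and rng.random() < 1.0 - np.exp(-params.k_f * dt_ms):
            if log is not None:
                log.append(step, time_ms, "active-site", "react_fwd", "ATP+AMP")
            return LigandOccupancy(("product", "product"))
    elif is_competent(coords, occupancy, model, sites, "reverse", params.q_min):
        if params.k_r > 0 and rng.random() < 1.0 - np.exp(-params.k_r * dt_ms):
            if log is not None:
                log.append(step, time_ms, "active-site", "react_rev", "2ADP")
            return LigandOccupancy(("substrate", "substrate"))
    return occupancy
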