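"""Multi-basin energy landscape: smooth interpolation of two single-basin
potentials per moving subsystem.

The enzyme is decomposed into a rigid core plus three double-basin terms
(LID-CORE, NMP-CORE, LID-NMP). Each double-basin term mixes an "open" and a
"closed" restricted sub-potential through

    V_DB = (V1 + V2 + dV)/2 - sqrt(((V1 - V2 - dV)/2)^2 + Delta^2)

where ``dV`` sets the open/closed energy gap (positive values penalize the
closed basin) and ``Delta`` lowers the barrier between the basins. Forces
follow by the chain rule with mixing weights in [0, 1].

Conformations are classified from the LID-CORE and NMP-CORE center-of-mass
distances against midpoint thresholds, yielding four states: open, closed,
and the two single-domain-open intermediates.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import geometry
from .energy import (
    SingleBasinParams,
    excluded_volume_energy,
    exv_candidate_pairs,
    _gaussian_well,
)
from .structure import BeadChain, ContactSet, ReferenceConformation

__all__ = [
    "SubPotential",
    "DoubleBasinTerm",
    "MultiBasinModel",
    "double_basin_energy",
    "build_multibasin_model",
    "total_energy",
    "classify_conformation",
    "com_distances",
    "STATE_LABELS",
]

CORE_TAG = "CORE"
DB_TAGS = ("LID-CORE", "NMP-CORE", "LID-NMP")
STATE_LABELS = ("closed", "open", "intermediate-LID-open", "intermediate-NMP-open")


@dataclass
class SubPotential:
    """A single-basin potential restricted to the elements of one subsystem."""

    bond_sel: np.ndarray  # indices into the chain's bond list
    b0: np.ndarray
    angle_sel: np.ndarray
    theta0: np.ndarray
    dihedral_sel: np.ndarray
    phi0: np.ndarray
    contacts: ContactSet

    def energy(self, coords: np.ndarray, p: SingleBasinParams):
        """Energy and gradient of the restricted terms (no flexible prior)."""
        n = len(coords)
        grad = np.zeros_like(coords)
        energy = 0.0

        if len(self.bond_sel):
            i = self.bond_sel
            d = coords[i + 1] - coords[i]
            b = np.linalg.norm(d, axis=1)
            db = b - self.b0
            energy += float(p.k_bond * np.sum(db**2))
            f = (2.0 * p.k_bond * db / np.maximum(b, 1e-12))[:, None] * d
            np.add.at(grad, i, -f)
            np.add.at(grad, i + 1, f)

        if len(self.angle_sel):
            theta, ga, gb, gc = geometry.angle_gradients(coords)
            s = self.angle_sel
            e, de = _gaussian_well(theta[s] - self.theta0, p.eps_angle, p.w_theta)
            energy += float(np.sum(e))
            np.add.at(grad, s, de[:, None] * ga[s])
            np.add.at(grad, s + 1, de[:, None] * gb[s])
            np.add.at(grad, s + 2, de[:, None] * gc[s])

        if len(self.dihedral_sel):
            phi, g0, g1, g2, g3 = geometry.dihedral_gradients(coords)
            s = self.dihedral_sel
            dph = geometry.wrap_angle(phi[s] - self.phi0)
            e, de = _gaussian_well(dph, p.eps_dihedral, p.w_phi)
            energy += float(np.sum(e))
            np.add.at(grad, s, de[:, None] * g0[s])
            np.add.at(grad, s + 1, de[:, None] * g1[s])
            np.add.at(grad, s + 2, de[:, None] * g2[s])
            np.add.at(grad, s + 3, de[:, None] * g3[s])

        if len(self.contacts):
            i = self.contacts.pairs[:, 0] - 1
            j = self.contacts.pairs[:, 1] - 1
            d = coords[j] - coords[i]
            r = np.linalg.norm(d, axis=1)
            dr = r - self.contacts.r0
            g = np.exp(-(dr**2) / (2.0 * p.w_c**2))
            energy += float(np.sum(-self.contacts.eps * g))
            de = self.contacts.eps * g * dr / p.w_c**2
            f = (de / np.maximum(r, 1e-12))[:, None] * d
            np.add.at(grad, i, -f)
            np.add.at(grad, j, f)

        return energy, grad


@dataclass
class DoubleBasinTerm:
    subsystem_tag: str
    open_sub: SubPotential
    closed_sub: SubPotential
    dV: float  # kcal/mol; > 0 penalizes the closed basin
    Delta: float  # kcal/mol; > 0 smooths/lowers the barrier

    def __post_init__(self) -> None:
        if self.Delta < 0:
            raise ValueError("Delta must be non-negative")


@dataclass
class MultiBasinModel:
    open_ref: ReferenceConformation
    closed_ref: ReferenceConformation
    params: SingleBasinParams
    core_sub: SubPotential
    terms: list[DoubleBasinTerm]
    exv_pairs: np.ndarray  # global excluded-volume candidate pairs (0-based)
    flp_theta0: np.ndarray  # flexible-prior centers (open-reference natives)
    flp_phi0: np.ndarray
    r_star_lid: float  # classifier thresholds (A)
    r_star_nmp: float
    lid_mask: np.ndarray = field(default=None)
    nmp_mask: np.ndarray = field(default=None)
    core_mask: np.ndarray = field(default=None)

    @property
    def n_residues(self) -> int:
        return self.open_ref.n_residues

    def term(self, tag: str) -> DoubleBasinTerm:
        for t in self.terms:
            if t.subsystem_tag == tag:
                return t
        raise KeyError(tag)

    def set_energy_gap(self, dV: "float | dict[str, float]") -> None:
        """Set the open/closed energy gap of all (or selected) terms."""
        if isinstance(dV, dict):
            for tag, v in dV.items():
                self.term(tag).dV = float(v)
        else:
            for t in self.terms:
                t.dV = float(dV)

    def energy_gaps(self) -> dict[str, float]:
        return {t.subsystem_tag: t.dV for t in self.terms}

    def set_barrier(self, Delta: float) -> None:
        for t in self.terms:
            t.Delta = float(Delta)


def double_basin_energy(V1: float, V2: float, dV: float, Delta: float):
    """Smoothly mixed two-basin energy and the basin-1 mixing weight.

    Returns ``(V_DB, w1)`` where forces compose as ``w1*F1 + (1-w1)*F2``.
    ``V_DB <= min(V1, V2 + dV)``, with equality only at ``Delta = 0``.
    """
    if Delta < 0:
        raise ValueError("Delta must be non-negative")
    u = 0.5 * (V1 - V2 - dV)
    s = np.hypot(u, Delta)
    v = 0.5 * (V1 + V2 + dV) - s
    if s == 0.0:
        w1 = 0.5
    else:
        w1 = 0.5 * (1.0 - u / s)
    return v, w1


def _element_owner(labels: np.ndarray, beads: range) -> str:
    labs = {labels[k] for k in beads}
    has_lid = "LID" in labs
    has_nmp = "NMP" in labs
    if has_lid and has_nmp:
        return "LID-NMP"
    if has_lid:
        return "LID-CORE"
    if has_nmp:
        return "NMP-CORE"
    return CORE_TAG


def _contact_owner(labels: np.ndarray, I: int, J: int) -> str:
    a, b = labels[I - 1], labels[J - 1]
    pair = {a, b}
    if pair == {"CORE"}:
        return CORE_TAG
    if pair <= {"LID", "CORE"}:
        return "LID-CORE"
    if pair <= {"NMP", "CORE"}:
        return "NMP-CORE"
    return "LID-NMP"


def _restrict(ref: ReferenceConformation, labels: np.ndarray, owner: str,
              eps_contact: float) -> SubPotential:
    n = ref.n_residues
    bond_sel = np.array(
        [i for i in range(n - 1) if _element_owner(labels, range(i, i + 2)) == owner],
        dtype=np.int64,
    )
    angle_sel = np.array(
        [i for i in range(n - 2) if _element_owner(labels, range(i, i + 3)) == owner],
        dtype=np.int64,
    )
    dih_sel = np.array(
        [i for i in range(n - 3) if _element_owner(labels, range(i, i + 4)) == owner],
        dtype=np.int64,
    )
    keep = np.array(
        [_contact_owner(labels, I, J) == owner for I, J in ref.contacts.pairs], dtype=bool
    ) if len(ref.contacts) else np.zeros(0, dtype=bool)
    contacts = ref.contacts.select(keep)
    contacts = ContactSet(
        contacts.pairs,
        contacts.r0,
        np.full(len(contacts), eps_contact),
        np.asarray([owner] * len(contacts), dtype=object),
    )
    return SubPotential(
        bond_sel=bond_sel,
        b0=ref.b0[bond_sel],
        angle_sel=angle_sel,
        theta0=ref.theta0[angle_sel],
        dihedral_sel=dih_sel,
        phi0=ref.phi0[dih_sel],
        contacts=contacts,
    )


def build_multibasin_model(
    open_ref: ReferenceConformation,
    closed_ref: ReferenceConformation,
    params: SingleBasinParams | None = None,
    dV: float = 0.0,
    Delta: float = 2.0,
    interface_eps_scale: float = 0.5,
    closed_interface_boost: float = 1.0,
) -> MultiBasinModel:
    """Partition the protein into core + three double-basin subsystems.

    Ownership is unique: intra-CORE elements and contacts form the core
    single-basin term (open-reference natives; the core is nearly identical
    in both crystal forms); every element touching one moving domain joins
    that domain's double-basin term; LID-NMP contacts form the coupling
    term. Excluded volume and the flexible prior are single global terms.
    """
    params = params or SingleBasinParams()
    if open_ref.n_residues != closed_ref.n_residues:
        raise ValueError("open and closed references differ in length")
    labels = open_ref.beads.domain_label
    if labels is None or closed_ref.beads.domain_label is None:
        raise ValueError("references need domain labels (assign_domains)")
    if not all(a == b for a, b in zip(labels, closed_ref.beads.domain_label)):
        raise ValueError("domain labels differ between references")

    core_sub = _restrict(open_ref, labels, CORE_TAG, params.eps_contact)
    terms = []
    for tag in DB_TAGS:
        sub_o = _restrict(open_ref, labels, tag, params.eps_contact)
        sub_c = _restrict(closed_ref, labels, tag, params.eps_contact)
        # cross-domain (interface) contacts may be weighted differently from
        # intra-domain ones: softer interfaces keep the docked states
        # kinetically escapable while the count still encodes the geometry
        for sub, boost in ((sub_o, 1.0), (sub_c, closed_interface_boost)):
            cross = np.array([
                labels[i - 1] != labels[j - 1] for i, j in sub.contacts.pairs
            ], dtype=bool) if len(sub.contacts) else np.zeros(0, dtype=bool)
            sub.contacts.eps[cross] *= interface_eps_scale * boost
        terms.append(DoubleBasinTerm(tag, sub_o, sub_c, dV=dV, Delta=Delta))

    # global excluded volume: exclude native contacts of either reference
    excl = {tuple(p) for p in open_ref.contacts.pairs}
    excl |= {tuple(p) for p in closed_ref.contacts.pairs}
    exv_pairs = exv_candidate_pairs(open_ref.n_residues, excl)

    chain_o, chain_c = open_ref.beads, closed_ref.beads
    r_lid_o, r_nmp_o = com_distances(chain_o.coords, chain_o)
    r_lid_c, r_nmp_c = com_distances(chain_c.coords, chain_o)
    model = MultiBasinModel(
        open_ref=open_ref,
        closed_ref=closed_ref,
        params=params,
        core_sub=core_sub,
        terms=terms,
        exv_pairs=exv_pairs,
        flp_theta0=open_ref.theta0,
        flp_phi0=open_ref.phi0,
        r_star_lid=0.5 * (r_lid_o + r_lid_c),
        r_star_nmp=0.5 * (r_nmp_o + r_nmp_c),
        lid_mask=chain_o.domain_mask("LID"),
        nmp_mask=chain_o.domain_mask("NMP"),
        core_mask=chain_o.domain_mask("CORE"),
    )
    return model


def com_distances(coords: np.ndarray, chain: BeadChain):
    """(R_LID-CORE, R_NMP-CORE) center-of-mass distances, uniform masses."""
    core = coords[chain.domain_mask("CORE")].mean(axis=0)
    r_lid = float(np.linalg.norm(coords[chain.domain_mask("LID")].mean(axis=0) - core))
    r_nmp = float(np.linalg.norm(coords[chain.domain_mask("NMP")].mean(axis=0) - core))
    return r_lid, r_nmp


def classify_conformation(coords: np.ndarray, model: MultiBasinModel) -> str:
    """Four-state label from the two COM distances vs midpoint thresholds."""
    core = coords[model.core_mask].mean(axis=0)
    r_lid = np.linalg.norm(coords[model.lid_mask].mean(axis=0) - core)
    r_nmp = np.linalg.norm(coords[model.nmp_mask].mean(axis=0) - core)
    lid_closed = r_lid < model.r_star_lid
    nmp_closed = r_nmp < model.r_star_nmp
    if lid_closed and nmp_closed:
        return "closed"
    if not lid_closed and not nmp_closed:
        return "open"
    if lid_closed:
        return "intermediate-NMP-open"
    return "intermediate-LID-open"


def total_energy(
    coords: np.ndarray,
    model: MultiBasinModel,
    occupancy=None,
    sites=None,
):
    """Full dynamic-landscape energy, gradient and per-term breakdown.

    Ligand terms contribute only for sites occupied in ``occupancy``
    (see :mod:`enzscape.ligand`).
    """
    from .ligand import binding_energy_gradient  # local import, no cycle at module load

    coords = np.asarray(coords, dtype=np.float64)
    p = model.params
    breakdown: dict[str, float] = {}

    energy, grad = model.core_sub.energy(coords, p)
    breakdown["core"] = energy

    for t in model.terms:
        e1, g1 = t.open_sub.energy(coords, p)
        e2, g2 = t.closed_sub.energy(coords, p)
        v, w1 = double_basin_energy(e1, e2, t.dV, t.Delta)
        energy += v
        grad += w1 * g1 + (1.0 - w1) * g2
        breakdown[t.subsystem_tag] = v
        breakdown[f"{t.subsystem_tag}:w_open"] = w1

    # global flexible-local prior (broad Gaussians at open-reference natives)
    if p.eps_flp > 0:
        n = len(coords)
        theta, ga, gb, gc = geometry.angle_gradients(coords)
        e, de = _gaussian_well(theta - model.flp_theta0, p.eps_flp, 2.0 * p.w_theta)
        energy += float(np.sum(e))
        breakdown["flp"] = float(np.sum(e))
        np.add.at(grad, np.arange(n - 2), de[:, None] * ga)
        np.add.at(grad, np.arange(1, n - 1), de[:, None] * gb)
        np.add.at(grad, np.arange(2, n), de[:, None] * gc)
        phi, g0, g1, g2, g3 = geometry.dihedral_gradients(coords)
        dph = geometry.wrap_angle(phi - model.flp_phi0)
        e, de = _gaussian_well(dph, p.eps_flp, 2.0 * p.w_phi)
        energy += float(np.sum(e))
        breakdown["flp"] += float(np.sum(e))
        np.add.at(grad, np.arange(n - 3), de[:, None] * g0)
        np.add.at(grad, np.arange(1, n - 2), de[:, None] * g1)
        np.add.at(grad, np.arange(2, n - 1), de[:, None] * g2)
        np.add.at(grad, np.arange(3, n), de[:, None] * g3)

    e_exv, g_exv = excluded_volume_energy(coords, model.exv_pairs, p)
    energy += e_exv
    grad += g_exv
    breakdown["exv"] = e_exv

    if occupancy is not None and sites is not None:
        e_lig = 0.0
        for site, species in zip(sites, occupancy.species):
            if species == "empty":
                continue
            e, g = binding_energy_gradient(coords, site, species)
            e_lig += e
            grad += g
        energy += e_lig
        breakdown["ligand"] = e_lig

    return energy, grad, breakdown
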