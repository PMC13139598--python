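"""Flatten a model + sites + chemistry + crowders into kernel arrays."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BEAD_MASS
from .ligand import BindingSite, SASA_PROBE, SASA_RADIUS, SASA_N_POINTS, sphere_points
from .multibasin import DB_TAGS, MultiBasinModel
from .reaction import ChemistryParams

__all__ = ["PackedSystem", "pack_system"]

_OWNER_CODE = {"CORE": 0, "LID-CORE": 1, "NMP-CORE": 2, "LID-NMP": 3}


@dataclass
class PackedSystem:
    """Plain-array view of the full system consumed by the compiled kernels."""

    n: int
    bond_owner: np.ndarray
    b0s: np.ndarray
    ang_owner: np.ndarray
    th0s: np.ndarray
    dih_owner: np.ndarray
    ph0s: np.ndarray
    ph0_cs: np.ndarray  # (n-3, 4): cos/sin of open and closed native dihedrals
    flp_th0: np.ndarray
    flp_ph0: np.ndarray
    cont_i: np.ndarray
    cont_j: np.ndarray
    cont_r0: np.ndarray
    cont_eps: np.ndarray
    cont_owner: np.ndarray
    cont_basin: np.ndarray
    dV: np.ndarray
    Delta: np.ndarray
    excl: np.ndarray
    lig_i: np.ndarray
    lig_j: np.ndarray
    lig_r0s: np.ndarray
    lig_eps: np.ndarray
    lig_site: np.ndarray
    pocket_idx: np.ndarray
    pocket_site: np.ndarray
    sphere: np.ndarray
    sasa_radius: float
    site_S0: np.ndarray
    site_sigS: np.ndarray
    site_kon0: np.ndarray
    site_koff0: np.ndarray
    site_conc: np.ndarray
    kf: float
    kr: float
    qmin: float
    lid_idx: np.ndarray
    nmp_idx: np.ndarray
    core_idx: np.ndarray
    pp: np.ndarray
    mass_p: float
    mass_c: float


def _element_owner_codes(model: MultiBasinModel, kind: str, count: int) -> np.ndarray:
    owner = np.zeros(count, dtype=np.int64)
    attr = {"bond": "bond_sel", "angle": "angle_sel", "dihedral": "dihedral_sel"}[kind]
    for t in model.terms:
        code = _OWNER_CODE[t.subsystem_tag]
        owner[getattr(t.open_sub, attr)] = code
    return owner


def pack_system(
    model: MultiBasinModel,
    sites: list[BindingSite] | None = None,
    chemistry: ChemistryParams | None = None,
    concentrations: dict[str, float] | None = None,
    crowder_radius: float = 8.0,
    merge_tol: float = 1e-9,
) -> PackedSystem:
    """Flatten the model for the kernel, exactly merging degenerate elements.

    A local element or contact whose open and closed natives coincide (to
    ``merge_tol``) contributes identically to both basins of its term;
    because ``V_DB(V1 + c, V2 + c) = V_DB(V1, V2) + c`` it can be moved into
    the unmixed core term without changing energies or forces. This halves
    the work for models whose moving parts are internally rigid.
    """
    n = model.n_residues
    p = model.params
    open_ref, closed_ref = model.open_ref, model.closed_ref

    b0s = np.stack([open_ref.b0, closed_ref.b0], axis=1)
    th0s = np.stack([open_ref.theta0, closed_ref.theta0], axis=1)
    ph0s = np.stack([open_ref.phi0, closed_ref.phi0], axis=1)
    ph0_cs = np.stack(
        [np.cos(open_ref.phi0), np.sin(open_ref.phi0),
         np.cos(closed_ref.phi0), np.sin(closed_ref.phi0)], axis=1
    )
    # the kernel evaluates the flexible prior at the basin-0 (open) natives
    if not (np.allclose(model.flp_theta0, open_ref.theta0)
            and np.allclose(model.flp_phi0, open_ref.phi0)):
        raise ValueError("flexible-prior centers must equal the open-reference natives")

    bond_owner = _element_owner_codes(model, "bond", n - 1)
    ang_owner = _element_owner_codes(model, "angle", n - 2)
    dih_owner = _element_owner_codes(model, "dihedral", n - 3)

    # exact merge of elements with identical open/closed natives
    bond_owner[np.abs(b0s[:, 0] - b0s[:, 1]) < merge_tol] = 0
    ang_owner[np.abs(th0s[:, 0] - th0s[:, 1]) < merge_tol] = 0
    dphi = np.abs(np.mod(ph0s[:, 0] - ph0s[:, 1] + np.pi, 2 * np.pi) - np.pi)
    dih_owner[dphi < merge_tol] = 0

    # merged contact list
    ci, cj, cr0, ceps, cown, cbas = [], [], [], [], [], []

    def add_contact_row(i, j, r0, eps, owner, basin):
        ci.append(i)
        cj.append(j)
        cr0.append(r0)
        ceps.append(eps)
        cown.append(owner)
        cbas.append(basin)

    def add_contacts(contacts, owner, basin):
        for k in range(len(contacts)):
            add_contact_row(contacts.pairs[k, 0] - 1, contacts.pairs[k, 1] - 1,
                            contacts.r0[k], contacts.eps[k], owner, basin)

    add_contacts(model.core_sub.contacts, 0, 0)
    for t in model.terms:
        code = _OWNER_CODE[t.subsystem_tag]
        c_open, c_closed = t.open_sub.contacts, t.closed_sub.contacts
        closed_map = {
            (int(c_closed.pairs[k, 0]), int(c_closed.pairs[k, 1])): k
            for k in range(len(c_closed))
        }
        matched = set()
        for k in range(len(c_open)):
            key = (int(c_open.pairs[k, 0]), int(c_open.pairs[k, 1]))
            kc = closed_map.get(key)
            if (
                kc is not None
                and abs(c_open.r0[k] - c_closed.r0[kc]) < merge_tol
                and abs(c_open.eps[k] - c_closed.eps[kc]) < merge_tol
            ):
                add_contact_row(key[0] - 1, key[1] - 1, c_open.r0[k],
                                c_open.eps[k], 0, 0)
                matched.add(kc)
            else:
                add_contact_row(key[0] - 1, key[1] - 1, c_open.r0[k],
                                c_open.eps[k], code, 0)
        for k in range(len(c_closed)):
            if k not in matched:
                add_contact_row(int(c_closed.pairs[k, 0]) - 1,
                                int(c_closed.pairs[k, 1]) - 1,
                                c_closed.r0[k], c_closed.eps[k], code, 1)

    excl = np.ones((n, n), dtype=np.uint8)
    for i, j in model.exv_pairs:
        excl[i, j] = 0
        excl[j, i] = 0

    # ligand arrays
    li, lj, lr0, leps, lsite = [], [], [], [], []
    pocket_idx, pocket_site = [], []
    nsite = 2
    S0 = np.full(nsite, 1e9)
    sigS = np.full(nsite, 1.0)
    kon0 = np.zeros(nsite)
    koff0 = np.ones((nsite, 2))
    conc = np.zeros((nsite, 2))
    sigma_lig = 1.0
    if sites:
        if len(sites) != 2:
            raise ValueError("exactly two binding sites are expected")
        sigma_lig = sites[0].sigma
        concentrations = concentrations or {}
        for s_idx, site in enumerate(sites):
            for k in range(len(site.pairs)):
                li.append(site.pairs[k, 0] - 1)
                lj.append(site.pairs[k, 1] - 1)
                lr0.append((site.r0_substrate[k], site.r0_product[k]))
                leps.append((site.eps_substrate[k], site.eps_product[k]))
                lsite.append(s_idx)
            pocket_idx.extend((site.pocket_residues - 1).tolist())
            pocket_site.extend([s_idx] * len(site.pocket_residues))
            S0[s_idx] = site.S0
            sigS[s_idx] = site.sigma_S
            kon0[s_idx] = site.kon0
            koff0[s_idx, 0] = site.koff0_substrate
            koff0[s_idx, 1] = site.koff0_product
            conc[s_idx, 0] = concentrations.get(site.substrate_name, 0.0)
            conc[s_idx, 1] = concentrations.get(site.product_name, 0.0)

    chemistry = chemistry or ChemistryParams(k_f=0.0, k_r=0.0)

    pp = np.zeros(22)
    pp[0] = p.k_bond
    pp[1] = p.eps_angle
    pp[2] = p.eps_dihedral
    pp[3] = p.eps_flp
    pp[4] = p.w_theta
    pp[5] = p.w_phi
    pp[6] = p.w_c
    pp[7] = p.eps_exv
    pp[8] = p.sigma_exv
    pp[9] = p.exv_cutoff_factor * p.sigma_exv
    pp[10] = sigma_lig
    # crowding slots 11-19 filled by the integrator from the CrowderSystem
    pp[20] = model.r_star_lid
    pp[21] = model.r_star_nmp

    dV = np.array([model.term(tag).dV for tag in DB_TAGS])
    Delta = np.array([model.term(tag).Delta for tag in DB_TAGS])

    return PackedSystem(
        n=n,
        bond_owner=bond_owner,
        b0s=b0s,
        ang_owner=ang_owner,
        th0s=th0s,
        dih_owner=dih_owner,
        ph0s=ph0s,
        ph0_cs=ph0_cs,
        flp_th0=model.flp_theta0.copy(),
        flp_ph0=model.flp_phi0.copy(),
        cont_i=np.asarray(ci, dtype=np.int64),
        cont_j=np.asarray(cj, dtype=np.int64),
        cont_r0=np.asarray(cr0, dtype=np.float64),
        cont_eps=np.asarray(ceps, dtype=np.float64),
        cont_owner=np.asarray(cown, dtype=np.int64),
        cont_basin=np.asarray(cbas, dtype=np.int64),
        dV=dV,
        Delta=Delta,
        excl=excl,
        lig_i=np.asarray(li, dtype=np.int64),
        lig_j=np.asarray(lj, dtype=np.int64),
        lig_r0s=np.asarray(lr0, dtype=np.float64).reshape(-1, 2),
        lig_eps=np.asarray(leps, dtype=np.float64).reshape(-1, 2),
        lig_site=np.asarray(lsite, dtype=np.int64),
        pocket_idx=np.asarray(pocket_idx, dtype=np.int64),
        pocket_site=np.asarray(pocket_site, dtype=np.int64),
        sphere=sphere_points(SASA_N_POINTS),
        sasa_radius=SASA_RADIUS + SASA_PROBE,
        site_S0=S0,
        site_sigS=sigS,
        site_kon0=kon0,
        site_koff0=koff0,
        site_conc=conc,
        kf=chemistry.k_f,
        kr=chemistry.k_r,
        qmin=chemistry.q_min,
        lid_idx=np.where(model.lid_mask)[0].astype(np.int64),
        nmp_idx=np.where(model.nmp_mask)[0].astype(np.int64),
        core_idx=np.where(model.core_mask)[0].astype(np.int64),
        pp=pp,
        mass_p=BEAD_MASS,
        mass_c=BEAD_MASS * (crowder_radius / SASA_RADIUS) ** 3,
    )
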