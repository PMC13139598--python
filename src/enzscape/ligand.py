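"""Implicit ligand binding: pocket energetics, SASA gating and the Metropolis
Monte Carlo exchange scheme.

Ligands are not explicit particles. A bound ligand manifests as a set of
attractive Gaussian restraints between pocket residue pairs at their
holo-structure distances: "anchor" pairs within one domain hold the ligand
regardless of conformation, while cross-domain "closure" pairs form only in
the closed state, so binding stabilizes closure and closure traps the
ligand. Binding and unbinding are sampled every ``mc_interval`` integration
steps from diffusion-limited rates gated by the pocket's solvent-accessible
surface area:

    k_on  = f(S) k_on0 [L]
    k_off = f(S) k_off0 exp(V_bind / kB T)      (V_bind <= 0)

with the logistic gate ``f(S) = 1 / (1 + exp(-(S - S0)/sigma_S))``. Event
probabilities over an interval dt are ``1 - exp(-k dt)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import KBT_300

__all__ = [
    "SPECIES",
    "BindingSite",
    "LigandOccupancy",
    "binding_energy",
    "binding_energy_gradient",
    "pocket_accessibility",
    "pocket_sasa",
    "sphere_points",
    "koff0_for_kd",
    "default_binding_sites",
    "mc_ligand_step",
]

SPECIES = ("empty", "substrate", "product")

#: bead radius (A) used for SASA: an effective Calpha-sphere
SASA_RADIUS = 3.4
SASA_PROBE = 1.4
SASA_N_POINTS = 240


@dataclass
class BindingSite:
    """One binding pocket with per-species implicit-ligand parameters."""

    site_id: str  # "ATP-site" | "AMP-site"
    pocket_residues: np.ndarray  # 1-based residue indices (for SASA)
    pairs: np.ndarray  # (m, 2) 1-based residue pairs
    r0_substrate: np.ndarray  # (m,) holo reference distances, A
    r0_product: np.ndarray
    eps_substrate: np.ndarray  # (m,) per-pair strengths, kcal/mol (> 0)
    eps_product: np.ndarray
    sigma: float = 1.0  # Gaussian width, A
    S0: float = 100.0  # gating midpoint, A^2
    sigma_S: float = 10.0  # gating steepness, A^2
    kon0: float = 10.0  # baseline rate, 1/(uM * ms)
    koff0_substrate: float = 1.0e3  # baseline release rates, 1/ms
    koff0_product: float = 1.0e3
    substrate_name: str = "ATP"
    product_name: str = "ADP"

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        for name in ("r0_substrate", "r0_product", "eps_substrate", "eps_product"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.ndim == 0:
                arr = np.full(len(self.pairs), float(arr))
            if len(arr) != len(self.pairs):
                raise ValueError(f"{name} length does not match pairs")
            setattr(self, name, arr)
        if np.any(self.eps_substrate < 0) or np.any(self.eps_product < 0):
            raise ValueError("binding strengths must be positive")
        if self.sigma <= 0 or self.sigma_S <= 0:
            raise ValueError("sigma and sigma_S must be positive")

    def r0(self, species: str) -> np.ndarray:
        if species == "substrate":
            return self.r0_substrate
        if species == "product":
            return self.r0_product
        raise ValueError(f"unknown species {species!r}")

    def eps(self, species: str) -> np.ndarray:
        if species == "substrate":
            return self.eps_substrate
        if species == "product":
            return self.eps_product
        raise ValueError(f"unknown species {species!r}")

    def koff0(self, species: str) -> float:
        return self.koff0_substrate if species == "substrate" else self.koff0_product

    def ligand_name(self, species: str) -> str:
        return self.substrate_name if species == "substrate" else self.product_name


@dataclass
class LigandOccupancy:
    """Occupancy of the two pockets; 3 x 3 = 9 reachable combinations."""

    species: tuple[str, str] = ("empty", "empty")

    def __post_init__(self) -> None:
        if len(self.species) != 2:
            raise ValueError("exactly two binding sites are modeled")
        for s in self.species:
            if s not in SPECIES:
                raise ValueError(f"unknown species {s!r}")
        self.species = tuple(self.species)

    @staticmethod
    def all_states() -> list["LigandOccupancy"]:
        return [LigandOccupancy((a, b)) for a in SPECIES for b in SPECIES]

    def with_site(self, idx: int, species: str) -> "LigandOccupancy":
        s = list(self.species)
        s[idx] = species
        return LigandOccupancy(tuple(s))

    @property
    def apo(self) -> bool:
        return self.species == ("empty", "empty")


def binding_energy(coords: np.ndarray, site: BindingSite, species: str) -> float:
    """Implicit-ligand stabilization, always <= 0; 0 only far from the pocket."""
    if species == "empty":
        raise ValueError("binding energy of an empty site is not defined")
    i = site.pairs[:, 0] - 1
    j = site.pairs[:, 1] - 1
    r = np.linalg.norm(coords[j] - coords[i], axis=1)
    dr = r - site.r0(species)
    return float(np.sum(-site.eps(species) * np.exp(-(dr**2) / (2.0 * site.sigma**2))))


def binding_energy_gradient(coords: np.ndarray, site: BindingSite, species: str):
    """Energy and gradient of the implicit-ligand term."""
    grad = np.zeros_like(coords)
    i = site.pairs[:, 0] - 1
    j = site.pairs[:, 1] - 1
    d = coords[j] - coords[i]
    r = np.linalg.norm(d, axis=1)
    dr = r - site.r0(species)
    eps = site.eps(species)
    g = np.exp(-(dr**2) / (2.0 * site.sigma**2))
    energy = float(np.sum(-eps * g))
    de = eps * g * dr / site.sigma**2
    f = (de / np.maximum(r, 1e-12))[:, None] * d
    np.add.at(grad, i, -f)
    np.add.at(grad, j, f)
    return energy, grad


def pocket_accessibility(S: float, site: BindingSite) -> float:
    """Logistic gate in (0, 1), monotone increasing in the pocket SASA."""
    if S < 0:
        raise ValueError("SASA must be non-negative")
    return float(1.0 / (1.0 + np.exp(-(S - site.S0) / site.sigma_S)))


def sphere_points(n: int = SASA_N_POINTS) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5**0.5) * k
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def pocket_sasa(coords: np.ndarray, site: BindingSite, n_points: int = SASA_N_POINTS) -> float:
    """Shrake-Rupley accessible area (A^2) summed over the pocket beads.

    Every bead is a sphere of radius ``SASA_RADIUS``; the probe adds
    ``SASA_PROBE``. The test-point set is deterministic.
    """
    pts = sphere_points(n_points)
    R = SASA_RADIUS + SASA_PROBE
    total = 0.0
    n = len(coords)
    for res in site.pocket_residues:
        center = coords[res - 1]
        d = np.linalg.norm(coords - center, axis=1)
        nbr = np.where((d < 2.0 * R) & (d > 1e-9))[0]
        surf = center + R * pts
        buried = np.zeros(len(pts), dtype=bool)
        for k in nbr:
            buried |= np.linalg.norm(surf - coords[k], axis=1) < R
        total += 4.0 * np.pi * R**2 * (1.0 - buried.mean())
    return float(total)


def koff0_for_kd(kd_um: float, kon0: float, anchor_depth: float,
                 kbt: float = KBT_300) -> float:
    """Baseline release rate reproducing a dissociation constant.

    For a pocket whose accessible-state binding energy is ``-anchor_depth``
    the two-state equilibrium gives ``K_d = (koff0/kon0) exp(-A/kBT)``,
    hence ``koff0 = K_d kon0 exp(A/kBT)``. The gate f(S) cancels from the
    ratio, so the calibration holds for any frozen accessible conformation.
    """
    if kd_um <= 0 or kon0 <= 0:
        raise ValueError("kd and kon0 must be positive")
    return float(kd_um * kon0 * np.exp(anchor_depth / kbt))


def default_binding_sites(
    model,
    closure_band: tuple[float, float] = (8.0, 11.0),
    substrate_anchor_depth: float = 3.0,
    substrate_closure_depth: float = 3.0,
    product_anchor_depth: float = 1.5,
    product_closure_depth: float = 1.5,
    kd_substrate: tuple[float, float] = (50.0, 200.0),  # uM (ATP-site, AMP-site)
    kd_product: float = 500.0,  # uM
    kon0: float = 10.0,  # 1/(uM ms)
    sigma: float = 1.5,
    kbt: float = KBT_300,
    max_closure_pairs: int = 12,
    max_anchor_pairs: int = 12,
) -> list[BindingSite]:
    """Construct the two pockets of a labeled two-state model.

    Closure pairs are cross-interface residue pairs whose closed-structure
    separation lies just beyond the native-contact cutoff (they interact
    through the bridging ligand, not directly); anchor pairs are
    intra-domain pairs of the same pocket region, formed in either
    conformation. Depths are split evenly over the pairs of each group so
    the holo-state stabilization equals ``anchor + closure`` depth. The
    gating midpoint S0 is half the open-reference pocket SASA; baseline
    release rates reproduce the configured dissociation constants.
    """
    closed = model.closed_ref.beads
    labels = closed.domain_label
    coords_c = closed.coords
    n = len(coords_c)
    d = np.linalg.norm(coords_c[:, None] - coords_c[None, :], axis=-1)
    lo, hi = closure_band

    sites = []
    for site_id, arm, kd_s, substrate in (
        ("ATP-site", "LID", kd_substrate[0], "ATP"),
        ("AMP-site", "NMP", kd_substrate[1], "AMP"),
    ):
        ii, jj = np.triu_indices(n, k=5)
        band = (d[ii, jj] > lo) & (d[ii, jj] <= hi)
        cross = np.array(
            [
                {labels[a], labels[b]} == {arm, "CORE"}
                for a, b in zip(ii, jj)
            ]
        )
        closure_sel = band & cross
        cpairs = np.stack([ii[closure_sel] + 1, jj[closure_sel] + 1], axis=1)
        if len(cpairs) == 0:
            raise ValueError(f"no closure pairs found for {site_id}")
        # keep the tightest pairs: the ligand bridges the narrowest part of
        # the interface
        cdist = d[cpairs[:, 0] - 1, cpairs[:, 1] - 1]
        cpairs = cpairs[np.argsort(cdist)[:max_closure_pairs]]
        pocket = np.unique(cpairs)
        in_pocket = np.isin(ii + 1, pocket) & np.isin(jj + 1, pocket)
        same_dom = np.array([labels[a] == labels[b] for a, b in zip(ii, jj)])
        anchor_sel = band & in_pocket & same_dom
        apairs = np.stack([ii[anchor_sel] + 1, jj[anchor_sel] + 1], axis=1)
        adist = d[apairs[:, 0] - 1, apairs[:, 1] - 1] if len(apairs) else np.empty(0)
        apairs = apairs[np.argsort(adist)[:max_anchor_pairs]]
        pairs = np.concatenate([cpairs, apairs], axis=0)
        r0 = d[pairs[:, 0] - 1, pairs[:, 1] - 1]

        def depths(anchor_depth, closure_depth):
            eps = np.empty(len(pairs))
            eps[: len(cpairs)] = closure_depth / len(cpairs)
            if len(apairs):
                eps[len(cpairs):] = anchor_depth / len(apairs)
            return eps

        site = BindingSite(
            site_id=site_id,
            pocket_residues=pocket,
            pairs=pairs,
            r0_substrate=r0,
            r0_product=r0,
            eps_substrate=depths(substrate_anchor_depth, substrate_closure_depth),
            eps_product=depths(product_anchor_depth, product_closure_depth),
            sigma=sigma,
            kon0=kon0,
            substrate_name=substrate,
            product_name="ADP",
        )
        # gate midpoint between the open and closed reference pocket areas:
        # accessible when open, shut (trapping the ligand) when closed
        s_open = pocket_sasa(model.open_ref.beads.coords, site)
        s_closed = pocket_sasa(model.closed_ref.beads.coords, site)
        site.S0 = 0.5 * (s_open + s_closed)
        site.sigma_S = max(0.12 * (s_open - s_closed), 1.0)
        anchor_eff = substrate_anchor_depth if len(apairs) else 0.0
        site.koff0_substrate = koff0_for_kd(kd_s, kon0, anchor_eff, kbt)
        site.koff0_product = koff0_for_kd(
            kd_product, kon0, product_anchor_depth if len(apairs) else 0.0, kbt
        )
        sites.append(site)
    return sites


def mc_ligand_step(
    coords: np.ndarray,
    occupancy: LigandOccupancy,
    sites: list[BindingSite],
    concentrations: dict[str, float],
    dt_ms: float,
    rng: np.random.Generator,
    kbt: float = KBT_300,
    log=None,
    step: int = 0,
    time_ms: float = 0.0,
):
    """One Metropolis MC exchange attempt per site (reference implementation).

    Empty sites draw a candidate species proportional to its on-rate and
    accept with ``1 - exp(-k_on_total dt)``; occupied sites release with
    ``1 - exp(-k_off dt)``. At most one event per site per call. Returns the
    (possibly new) occupancy.
    """
    new = occupancy
    for idx, site in enumerate(sites):
        S = pocket_sasa(coords, site)
        fS = pocket_accessibility(S, site)
        species = occupancy.species[idx]
        if species == "empty":
            kons = {}
            for sp in ("substrate", "product"):
                conc = concentrations.get(site.ligand_name(sp), 0.0)
                kons[sp] = fS * site.kon0 * conc
            ktot = sum(kons.values())
            if ktot <= 0.0:
                continue
            p = 1.0 - np.exp(-ktot * dt_ms)
            if rng.random() < p:
                pick = rng.random() * ktot
                sp = "substrate" if pick < kons["substrate"] else "product"
                new = new.with_site(idx, sp)
                if log is not None:
                    log.append(step, time_ms, site.site_id, "bind",
                               site.ligand_name(sp), S, fS,
                               binding_energy(coords, site, sp))
        else:
            e_bind = binding_energy(coords, site, species)
            koff = fS * site.koff0(species) * np.exp(e_bind / kbt)
            p = 1.0 - np.exp(-koff * dt_ms)
            if rng.random() < p:
                new = new.with_site(idx, "empty")
                if log is not None:
                    log.append(step, time_ms, site.site_id, "unbind",
                               site.ligand_name(species), S, fS, e_bind)
    return new
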