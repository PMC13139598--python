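"""Implicit ligand energetics, SASA gating, and the MC exchange scheme."""
import numpy as np
import pytest

from enzscape.constants import KBT_300
from enzscape.ligand import (
    BindingSite,
    LigandOccupancy,
    binding_energy,
    binding_energy_gradient,
    default_binding_sites,
    koff0_for_kd,
    mc_ligand_step,
    pocket_accessibility,
    pocket_sasa,
)


@pytest.fixture()
def simple_site():
    """Four beads arranged so two pocket pairs sit exactly at r0 = 5 A."""
    coords = np.array([
        [0.0, 0.0, 0.0],
        [5.0, 0.0, 0.0],
        [0.0, 5.0, 0.0],
        [5.0, 5.0, 0.0],
    ])
    site = BindingSite(
        site_id="ATP-site",
        pocket_residues=np.array([1, 2, 3, 4]),
        pairs=np.array([[1, 2], [3, 4]]),
        r0_substrate=np.array([5.0, 5.0]),
        r0_product=np.array([5.0, 5.0]),
        eps_substrate=np.array([1.5, 1.5]),
        eps_product=np.array([0.75, 0.75]),
        sigma=1.0,
        S0=100.0,
        sigma_S=10.0,
    )
    return coords, site


class TestOccupancy:
    def test_nine_reachable_combinations(self):
        states = LigandOccupancy.all_states()
        assert len(states) == 9
        assert len({s.species for s in states}) == 9

    def test_validation(self):
        with pytest.raises(ValueError):
            LigandOccupancy(("empty",))
        with pytest.raises(ValueError):
            LigandOccupancy(("empty", "water"))


class TestBindingEnergy:
    def test_holo_geometry_gives_full_depth(self, simple_site):
        coords, site = simple_site
        assert binding_energy(coords, site, "substrate") == pytest.approx(-3.0)
        assert binding_energy(coords, site, "product") == pytest.approx(-1.5)

    def test_three_sigma_displacement(self, simple_site):
        coords, site = simple_site
        moved = coords.copy()
        moved[1, 0] += 3.0 * site.sigma
        moved[3, 0] += 3.0 * site.sigma
        e = binding_energy(moved, site, "substrate")
        assert e == pytest.approx(-3.0 * np.exp(-4.5), rel=1e-9)

    def test_unknown_species_rejected(self, simple_site):
        coords, site = simple_site
        with pytest.raises(ValueError):
            binding_energy(coords, site, "empty")

    def test_gradient_matches_finite_differences(self, simple_site, rng):
        coords, site = simple_site
        coords = coords + rng.normal(0, 0.3, coords.shape)
        _, grad = binding_energy_gradient(coords, site, "substrate")
        h = 1e-6
        for i in range(4):
            for ax in range(3):
                p = coords.copy()
                p[i, ax] += h
                m = coords.copy()
                m[i, ax] -= h
                fd = (binding_energy(p, site, "substrate")
                      - binding_energy(m, site, "substrate")) / (2 * h)
                assert grad[i, ax] == pytest.approx(fd, abs=1e-6)


class TestAccessibilityGate:
    def test_midpoint(self, simple_site):
        _, site = simple_site
        assert pocket_accessibility(site.S0, site) == pytest.approx(0.5)

    def test_one_width_above(self, simple_site):
        _, site = simple_site
        f = pocket_accessibility(site.S0 + site.sigma_S, site)
        assert f == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-9)

    def test_saturation_and_monotonicity(self, simple_site):
        _, site = simple_site
        assert pocket_accessibility(site.S0 + 50 * site.sigma_S, site) > 1 - 1e-6
        ss = np.linspace(0, 400, 30)
        fs = [pocket_accessibility(s, site) for s in ss]
        assert np.all(np.diff(fs) > 0)
        with pytest.raises(ValueError):
            pocket_accessibility(-1.0, site)


class TestPocketSASA:
    def test_isolated_bead_full_sphere(self):
        site = BindingSite(
            site_id="ATP-site", pocket_residues=np.array([1]),
            pairs=np.array([[1, 2]]), r0_substrate=5.0, r0_product=5.0,
            eps_substrate=1.0, eps_product=1.0,
        )
        coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        S = pocket_sasa(coords, site)
        assert S == pytest.approx(4 * np.pi * 4.8**2, rel=1e-6)  # ~289.5 A^2

    def test_enclosed_bead_is_buried(self, rng):
        from enzscape.ligand import sphere_points

        shell = 4.0 * sphere_points(300)  # dense shell around the center bead
        coords = np.vstack([[[0.0, 0, 0]], shell])
        site = BindingSite(
            site_id="ATP-site", pocket_residues=np.array([1]),
            pairs=np.array([[1, 2]]), r0_substrate=4.0, r0_product=4.0,
            eps_substrate=1.0, eps_product=1.0,
        )
        assert pocket_sasa(coords, site) < 1.0

    def test_open_pocket_more_accessible_than_closed(self, adk_model):
        from enzscape.adk import build_enzyme_model

        system = build_enzyme_model()
        for site in system.sites:
            s_open = pocket_sasa(system.model.open_ref.beads.coords, site)
            s_closed = pocket_sasa(system.model.closed_ref.beads.coords, site)
            assert s_open > s_closed

    def test_kernel_sasa_matches_reference(self, adk_model):
        from enzscape import _kernels as K
        from enzscape.adk import build_enzyme_model
        from enzscape.ligand import SASA_N_POINTS, sphere_points

        system = build_enzyme_model()
        coords = system.model.closed_ref.beads.coords
        for site in system.sites:
            ref = pocket_sasa(coords, site)
            kern = K.pocket_sasa_kernel(
                coords, site.pocket_residues - 1, sphere_points(SASA_N_POINTS), 4.8
            )
            assert kern == pytest.approx(ref, rel=1e-9)


class TestKdCalibration:
    def test_koff0_reproduces_kd(self):
        # K_d = (koff0/kon0) exp(-A/kBT) must recover the requested value
        koff0 = koff0_for_kd(50.0, kon0=10.0, anchor_depth=3.0)
        kd = koff0 / 10.0 * np.exp(-3.0 / KBT_300)
        assert kd == pytest.approx(50.0, rel=1e-12)


class TestMCExchange:
    def test_zero_concentration_never_binds(self, simple_site, rng):
        coords, site = simple_site
        occ = LigandOccupancy(("empty", "empty"))
        sites = [site, site]
        for _ in range(200):
            occ = mc_ligand_step(coords, occ, sites,
                                 {"ATP": 0.0, "AMP": 0.0, "ADP": 0.0},
                                 dt_ms=1.0, rng=rng)
        assert occ.apo

    def test_closed_gate_blocks_everything(self, simple_site, rng):
        coords, site = simple_site
        site.S0 = 1e9  # f(S) ~ 0 regardless of geometry
        site.sigma_S = 1.0
        sites = [site, site]
        occ = LigandOccupancy(("substrate", "empty"))
        for _ in range(200):
            occ = mc_ligand_step(coords, occ, sites,
                                 {"ATP": 1e6, "AMP": 1e6, "ADP": 0.0},
                                 dt_ms=1.0, rng=rng)
        assert occ.species == ("substrate", "empty")

    def test_frozen_pocket_occupancy_matches_two_state_formula(self, simple_site):
        """Long-run occupied fraction of a rigid holo pocket equals
        k_on / (k_on + k_off) within 3 standard errors."""
        coords, site = simple_site
        site.S0 = 0.0
        site.sigma_S = 10.0  # f(S) ~ 1
        site.kon0 = 10.0
        site.koff0_substrate = koff0_for_kd(50.0, 10.0, 3.0)
        sites = [site, site]
        conc = {"ATP": 100.0, "AMP": 0.0, "ADP": 0.0}
        S = pocket_sasa(coords, site)
        fS = pocket_accessibility(S, site)
        kon = fS * site.kon0 * conc["ATP"]
        e_bind = binding_energy(coords, site, "substrate")
        koff = fS * site.koff0_substrate * np.exp(e_bind / KBT_300)
        expected = kon / (kon + koff)

        rng = np.random.default_rng(42)
        dt = 0.2 / max(kon, koff)  # resolve both rates
        occ = LigandOccupancy(("empty", "empty"))
        n_occ = 0
        n_tot = 4000
        for _ in range(n_tot):
            occ = mc_ligand_step(coords, occ, sites, conc, dt_ms=dt, rng=rng)
            n_occ += occ.species[0] != "empty"
        p_hat = n_occ / n_tot
        # effective samples ~ number of exchange events
        n_events = n_tot * dt * min(kon, koff) * 2
        se = np.sqrt(expected * (1 - expected) / max(n_events, 1))
        assert abs(p_hat - expected) < 3 * se + 0.02

    def test_acceptance_probability_bounds(self):
        # 1 - exp(-k dt) is a probability and never exceeds k dt
        for k, dt in [(0.1, 1.0), (10.0, 0.5), (1e4, 1e-3)]:
            p = 1.0 - np.exp(-k * dt)
            assert 0.0 <= p <= 1.0
            assert p <= k * dt

    def test_products_never_rebind_without_adp(self, simple_site, rng):
        coords, site = simple_site
        site.S0 = 0.0  # pocket always accessible
        sites = [site, site]
        conc = {"ATP": 0.0, "AMP": 0.0, "ADP": 0.0}
        occ = LigandOccupancy(("product", "product"))
        seen_rebind = False
        for _ in range(500):
            new = mc_ligand_step(coords, occ, sites, conc, dt_ms=0.01, rng=rng)
            if any(a == "empty" and b == "product"
                   for a, b in zip(occ.species, new.species)):
                seen_rebind = True
            occ = new
        assert occ.apo  # everything released eventually
        assert not seen_rebind


def test_default_sites_construction(adk_model):
    sites = default_binding_sites(adk_model)
    assert [s.site_id for s in sites] == ["ATP-site", "AMP-site"]
    for site in sites:
        assert len(site.pairs) > 0
        # closure pairs bridge distinct domains just beyond the contact cutoff
        labels = adk_model.open_ref.beads.domain_label
        cross = [
            labels[i - 1] != labels[j - 1] for i, j in site.pairs
        ]
        assert any(cross)
        assert np.all(site.r0_substrate > 8.0)
        assert np.all(site.r0_substrate <= 11.0)
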