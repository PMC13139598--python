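"""Double-basin mixing, state classification, and the term partition."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enzscape.ligand import LigandOccupancy
from enzscape.multibasin import (
    build_multibasin_model,
    classify_conformation,
    com_distances,
    double_basin_energy,
    total_energy,
)

finite = st.floats(min_value=-100.0, max_value=100.0, allow_nan=False)


class TestDoubleBasinFormula:
    def test_symmetric_crossing(self):
        # V1 = V2 + dV: both effective basins equal -> V_DB = V1 - Delta
        v, w = double_basin_energy(V1=-3.0, V2=-5.0, dV=2.0, Delta=1.0)
        assert v == pytest.approx(-4.0)
        assert w == pytest.approx(0.5)

    def test_zero_delta_reduces_to_min(self):
        v, w = double_basin_energy(V1=-5.0, V2=-3.0, dV=0.0, Delta=0.0)
        assert v == -5.0
        assert w == 1.0  # basin 1 is the minimum

    def test_plugged_in_value(self):
        v, _ = double_basin_energy(V1=0.0, V2=0.0, dV=4.0, Delta=2.0)
        assert v == pytest.approx(2.0 - np.sqrt(8.0), abs=1e-12)  # ~ -0.8284

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            double_basin_energy(0.0, 0.0, 0.0, -1.0)

    @settings(max_examples=300, deadline=None)
    @given(v1=finite, v2=finite, dv=finite,
           delta=st.floats(min_value=0.0, max_value=50.0, allow_nan=False))
    def test_below_min_of_basins(self, v1, v2, dv, delta):
        v, w = double_basin_energy(v1, v2, dv, delta)
        assert v <= min(v1, v2 + dv) + 1e-9
        if delta > 1e-6 and abs(v1 - v2 - dv) < 50:
            assert v < min(v1, v2 + dv)
        assert 0.0 <= w <= 1.0

    @settings(max_examples=100, deadline=None)
    @given(v1=finite, v2=finite, dv=finite,
           delta=st.floats(min_value=0.0, max_value=50.0, allow_nan=False))
    def test_gap_sensitivity_bounded(self, v1, v2, dv, delta):
        """dV_DB/d(dV) lies in [0, 1]: raising the gap never lowers the
        mixed energy and never raises it faster than linearly."""
        h = 1e-4
        vp, _ = double_basin_energy(v1, v2, dv + h, delta)
        vm, _ = double_basin_energy(v1, v2, dv - h, delta)
        deriv = (vp - vm) / (2 * h)
        assert -1e-6 <= deriv <= 1.0 + 1e-6


class TestModelPartition:
    def test_unique_ownership_of_elements(self, adk_model):
        n = adk_model.n_residues
        for kind, count in (("bond_sel", n - 1), ("angle_sel", n - 2),
                            ("dihedral_sel", n - 3)):
            owned = list(getattr(adk_model.core_sub, kind))
            for t in adk_model.terms:
                owned += list(getattr(t.open_sub, kind))
                # open/closed restrictions of one term cover the same elements
                np.testing.assert_array_equal(
                    getattr(t.open_sub, kind), getattr(t.closed_sub, kind)
                )
            assert sorted(owned) == list(range(count))

    def test_contacts_partitioned_once(self, adk_model, adk_refs):
        for ref, basin in ((adk_refs[0], "open_sub"), (adk_refs[1], "closed_sub")):
            pairs = []
            pairs += [tuple(p) for p in adk_model.core_sub.contacts.pairs]
            for t in adk_model.terms:
                pairs += [tuple(p) for p in getattr(t, basin).contacts.pairs]
            assert sorted(pairs) == sorted(tuple(p) for p in ref.contacts.pairs)

    def test_interface_contacts_only_in_closed_basin(self, adk_model):
        lid_core = adk_model.term("LID-CORE")
        assert len(lid_core.closed_sub.contacts) > len(lid_core.open_sub.contacts)
        assert len(adk_model.term("LID-NMP").closed_sub.contacts) > 0


class TestTotalEnergy:
    def test_apo_has_no_ligand_contribution(self, adk_model):
        from enzscape.adk import build_enzyme_model

        system = build_enzyme_model()
        coords = adk_model.open_ref.beads.coords
        e_apo, _, br = total_energy(coords, system.model,
                                    LigandOccupancy(("empty", "empty")),
                                    system.sites)
        assert br["ligand"] == 0.0

    def test_gradient_matches_finite_differences(self, adk_model, rng):
        coords = adk_model.open_ref.beads.coords + rng.normal(
            0, 0.05, (adk_model.n_residues, 3)
        )
        _, grad, _ = total_energy(coords, adk_model)
        h = 1e-5
        idx = rng.choice(adk_model.n_residues, size=25, replace=False)
        for i in idx:
            for ax in range(3):
                p = coords.copy()
                p[i, ax] += h
                m = coords.copy()
                m[i, ax] -= h
                fd = (total_energy(p, adk_model)[0] - total_energy(m, adk_model)[0]) / (2 * h)
                assert abs(grad[i, ax] - fd) < 1e-5

    def test_zero_barrier_recovers_min_rule(self, adk_refs):
        model = build_multibasin_model(*adk_refs, dV=0.0, Delta=0.0)
        coords = adk_refs[0].beads.coords
        e, _, br = total_energy(coords, model)
        # recompute via explicit per-term min over basins
        p = model.params
        expected = br["core"] + br["exv"] + br.get("flp", 0.0)
        for t in model.terms:
            e1, _ = t.open_sub.energy(coords, p)
            e2, _ = t.closed_sub.energy(coords, p)
            expected += min(e1, e2)
        assert e == pytest.approx(expected, abs=1e-9)


class TestClassifier:
    def test_reference_structures(self, adk_model, adk_refs):
        assert classify_conformation(adk_refs[0].beads.coords, adk_model) == "open"
        assert classify_conformation(adk_refs[1].beads.coords, adk_model) == "closed"

    def test_mixed_states_are_intermediates(self, adk_model, adk_refs):
        open_c, closed_c = adk_refs[0].beads.coords, adk_refs[1].beads.coords
        # LID closed (use closed coordinates for LID), NMP open
        hybrid = open_c.copy()
        lid = adk_model.lid_mask
        hybrid[lid] = closed_c[lid]
        assert classify_conformation(hybrid, adk_model) == "intermediate-NMP-open"
        hybrid2 = closed_c.copy()
        hybrid2[lid] = open_c[lid]
        assert classify_conformation(hybrid2, adk_model) == "intermediate-LID-open"

    def test_thresholds_are_midpoints(self, adk_model, adk_refs):
        r_lo, r_no = com_distances(adk_refs[0].beads.coords, adk_refs[0].beads)
        r_lc, r_nc = com_distances(adk_refs[1].beads.coords, adk_refs[0].beads)
        assert adk_model.r_star_lid == pytest.approx(0.5 * (r_lo + r_lc))
        assert adk_model.r_star_nmp == pytest.approx(0.5 * (r_no + r_nc))


def test_kernel_matches_reference_energies_and_forces(adk_model, rng):
    """The compiled engine and the NumPy reference implement one potential."""
    from enzscape import _kernels as K
    from enzscape.adk import build_enzyme_model
    from enzscape.packing import pack_system

    system = build_enzyme_model()
    model = system.model
    pk = pack_system(model, system.sites)
    n = pk.n
    pp = pk.pp.copy()
    pp[11:20] = [1.0, 1.0, 6.0, 16.0, 10.0, 0.0, 1e6, 10.0, 5.0]  # walls far away

    for occ_states in (("empty", "empty"), ("substrate", "substrate"),
                       ("product", "empty")):
        occ = np.array(
            [{"empty": 0, "substrate": 1, "product": 2}[s] for s in occ_states],
            dtype=np.int64,
        )
        coords = model.closed_ref.beads.coords + rng.normal(0, 0.1, (n, 3))
        e_ref, g_ref, _ = total_energy(coords, model, LigandOccupancy(occ_states),
                                       system.sites)
        F = np.zeros((n, 3))
        Fm = np.zeros((n, 3))
        Fc = np.zeros((0, 3))
        w_open = np.ones(4)
        bv = np.empty((n - 1, 4))
        ang_store = np.empty((n - 2, 12))
        dih_store = np.empty((n - 3, 14))
        cont_store = np.empty((len(pk.cont_i), 3))
        exv_pairs = np.empty((n * 120, 2), dtype=np.int64)
        n_exv = K.rebuild_exv_list(coords, pk.excl, 1e4, exv_pairs)
        pcp = np.empty((16, 2), dtype=np.int64)
        ccp = np.empty((16, 2), dtype=np.int64)
        e_k = K.compute_forces(
            coords, np.empty((0, 3)), F, Fc, pk.bond_owner, pk.b0s, pk.ang_owner,
            pk.th0s, pk.dih_owner, pk.ph0_cs, pk.cont_i, pk.cont_j, pk.cont_r0,
            pk.cont_eps, pk.cont_owner, pk.cont_basin, pk.dV, pk.Delta,
            exv_pairs, n_exv, occ, pk.lig_i, pk.lig_j, pk.lig_r0s, pk.lig_eps,
            pk.lig_site, pcp, 0, ccp, 0, pp, w_open, bv, ang_store, dih_store,
            cont_store, Fm,
        )
        assert e_k == pytest.approx(e_ref, abs=2e-5)
        assert np.abs(F - (-g_ref)).max() < 1e-5
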