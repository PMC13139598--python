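"""Coarse-grained chain construction, PDB I/O and native-contact detection."""
import numpy as np
import pytest

from enzscape.structure import (
    ADK_DOMAIN_RANGES,
    BeadChain,
    assign_domains,
    detect_native_contacts,
    load_calpha_model,
    make_reference,
    write_calpha_pdb,
)
from enzscape.synthetic import make_toy_two_state, toy_domain_ranges

THREE_RES_PDB = """\
ATOM      1  N   GLY A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


def test_three_residue_roundtrip():
    chain = load_calpha_model(THREE_RES_PDB, "A")
    assert chain.n_residues == 3
    np.testing.assert_allclose(
        chain.coords, [[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], atol=1e-6
    )
    assert list(chain.residue_name) == ["GLY", "ALA", "SER"]


def test_missing_interior_calpha_is_named():
    # residue 2 keeps a backbone nitrogen but loses its Calpha
    broken = THREE_RES_PDB.replace(
        "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C",
        "ATOM      3  N   ALA A   2       3.300   0.000   0.000  1.00  0.00           N",
    )
    with pytest.raises(ValueError, match="2"):
        load_calpha_model(broken, "A")


def test_missing_chain_and_insertion_codes():
    with pytest.raises(ValueError, match="chain"):
        load_calpha_model(THREE_RES_PDB, "B")
    with_icode = THREE_RES_PDB.replace("ALA A   2 ", "ALA A   2A")
    with pytest.raises(ValueError, match="insertion"):
        load_calpha_model(with_icode, "A")
    # remap table makes the insertion-code residue acceptable
    chain = load_calpha_model(with_icode, "A", icode_remap={(2, "A"): 2})
    assert chain.n_residues == 3


def test_altloc_resolved_by_occupancy():
    pdb = THREE_RES_PDB.replace(
        "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C",
        "ATOM      3  CA AALA A   2       3.800   0.000   0.000  0.40  0.00           C\n"
        "ATOM      4  CA BALA A   2       3.900   0.000   0.000  0.60  0.00           C",
    )
    chain = load_calpha_model(pdb, "A")
    assert chain.coords[1, 0] == pytest.approx(3.9, abs=1e-6)


def test_synthetic_enzyme_has_214_beads_and_roundtrips(adk_refs):
    open_ref, _ = adk_refs
    assert open_ref.n_residues == 214
    text = write_calpha_pdb(open_ref.beads)
    back = load_calpha_model(text, "A")
    assert back.n_residues == 214
    # PDB stores 3 decimals: round trip to within that precision
    np.testing.assert_allclose(back.coords, open_ref.beads.coords, atol=1e-3)


def test_domain_partition_covers_all_residues(adk_refs):
    chain = adk_refs[0].beads
    counts = {d: int(chain.domain_mask(d).sum()) for d in ("CORE", "NMP", "LID")}
    assert sum(counts.values()) == 214
    expected = {
        d: sum(hi - lo + 1 for lo, hi in ivs) for d, ivs in ADK_DOMAIN_RANGES.items()
    }
    assert counts == expected


def test_domain_assignment_toy_and_errors():
    chain = BeadChain(
        residue_index=np.arange(1, 11),
        residue_name=["GLY"] * 10,
        coords=np.column_stack([3.8 * np.arange(10), np.zeros(10), np.zeros(10)]),
    )
    labelled = assign_domains(
        chain, {"CORE": [(1, 4)], "NMP": [(5, 7)], "LID": [(8, 10)]}
    )
    assert list(labelled.domain_label) == ["CORE"] * 4 + ["NMP"] * 3 + ["LID"] * 3
    with pytest.raises(ValueError, match="cover"):
        assign_domains(chain, {"CORE": [(1, 8)]})
    with pytest.raises(ValueError, match="overlap"):
        assign_domains(chain, {"CORE": [(1, 6)], "LID": [(5, 10)]})


def test_contact_detection_geometry_rules():
    # collinear chain at 3.8 A spacing: the nearest |i-j| > 4 pair is 19 A
    coords = np.column_stack([3.8 * np.arange(12), np.zeros(12), np.zeros(12)])
    chain = BeadChain(np.arange(1, 13), ["GLY"] * 12, coords)
    assert len(detect_native_contacts(chain, cutoff=8.0)) == 0

    # two beads 6 A apart at sequence separation 5 -> one contact with r0 = 6
    coords2 = coords.copy()
    coords2[5] = coords2[0] + [0.0, 6.0, 0.0]
    # keep bonds legal is irrelevant to detection; only distances matter
    chain2 = BeadChain(np.arange(1, 13), ["GLY"] * 12, coords2)
    contacts = detect_native_contacts(chain2, cutoff=8.0)
    pair_list = [tuple(p) for p in contacts.pairs]
    assert (1, 6) in pair_list
    r0 = contacts.r0[pair_list.index((1, 6))]
    assert r0 == pytest.approx(6.0, abs=1e-9)

    # separation exactly 4 is excluded even at short distance
    coords3 = coords.copy()
    coords3[4] = coords3[0] + [0.0, 5.0, 0.0]
    chain3 = BeadChain(np.arange(1, 13), ["GLY"] * 12, coords3)
    assert (1, 5) not in [tuple(p) for p in detect_native_contacts(chain3, 8.0).pairs]


def test_contact_detection_matches_bruteforce(adk_refs):
    ref = adk_refs[1]
    contacts = detect_native_contacts(ref, cutoff=8.0)
    coords = ref.beads.coords
    n = len(coords)
    brute = set()
    for i in range(n):
        for j in range(i + 5, n):
            if np.linalg.norm(coords[i] - coords[j]) <= 8.0:
                brute.add((i + 1, j + 1))
    assert {tuple(p) for p in contacts.pairs} == brute


def test_reference_geometry_recomputable(adk_refs):
    from enzscape import geometry

    ref = adk_refs[0]
    np.testing.assert_allclose(ref.b0, geometry.bond_lengths(ref.beads.coords), rtol=1e-10)
    np.testing.assert_allclose(ref.theta0, geometry.bond_angles(ref.beads.coords), rtol=1e-10)


class TestToyTwoState:
    def test_deterministic(self):
        a = make_toy_two_state(20, 10.0, 1)
        b = make_toy_two_state(20, 10.0, 1)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.beads.coords, y.beads.coords)

    def test_zero_displacement_coincides(self):
        o, c = make_toy_two_state(20, 0.0, 1)
        np.testing.assert_allclose(o.beads.coords, c.beads.coords)

    def test_displacement_and_rmsd(self):
        o, c = make_toy_two_state(20, 10.0, 1)
        ranges = toy_domain_ranges(20)
        r_open = np.linalg.norm(o.beads.domain_com("LID") - o.beads.domain_com("CORE"))
        r_closed = np.linalg.norm(c.beads.domain_com("LID") - c.beads.domain_com("CORE"))
        assert r_open - r_closed == pytest.approx(10.0, abs=1e-3)
        rmsd = np.sqrt(((o.beads.coords - c.beads.coords) ** 2).sum(1).mean())
        assert rmsd > 2.0
        assert ranges["LID"][0][1] == 20

    def test_bond_lengths_shared_between_states(self):
        from enzscape import geometry

        o, c = make_toy_two_state(24, 16.0, 3)
        np.testing.assert_allclose(
            geometry.bond_lengths(o.beads.coords),
            geometry.bond_lengths(c.beads.coords),
            atol=1e-9,
        )

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_toy_two_state(7, 5.0, 1)
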