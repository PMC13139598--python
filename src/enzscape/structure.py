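"""Coarse-grained Calpha chain representation and native-contact detection.

A protein is reduced to one bead per residue, centered on the Calpha atom.
Two crystallographic reference conformations (an open and a closed form)
define the native geometry (bonds, angles, dihedrals, contact distances)
used by the structure-based potentials.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import geometry

__all__ = [
    "BeadChain",
    "ContactSet",
    "ReferenceConformation",
    "load_calpha_model",
    "write_calpha_pdb",
    "assign_domains",
    "detect_native_contacts",
    "make_reference",
]

DOMAIN_NAMES = ("CORE", "LID", "NMP")

#: Default three-domain partition for the 214-residue adenylate-kinase-like
#: chain: CORE = 1-29 u 68-117 u 161-214, NMP = 30-67, LID = 118-160.
ADK_DOMAIN_RANGES: dict[str, tuple[tuple[int, int], ...]] = {
    "CORE": ((1, 29), (68, 117), (161, 214)),
    "NMP": ((30, 67),),
    "LID": ((118, 160),),
}


@dataclass
class BeadChain:
    """One bead per residue, ordered by (1-based, contiguous) residue index."""

    residue_index: np.ndarray  # (n,) int
    residue_name: np.ndarray  # (n,) 3-letter codes
    coords: np.ndarray  # (n, 3) float, angstrom
    domain_label: np.ndarray | None = None  # (n,) str labels or None

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=np.int64)
        self.residue_name = np.asarray(self.residue_name, dtype=object)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        n = len(self.residue_index)
        if len(self.residue_name) != n or len(self.coords) != n:
            raise ValueError("field lengths are inconsistent")
        if n and not np.all(np.diff(self.residue_index) == 1):
            raise ValueError("residue indices must be strictly increasing and contiguous")

    def __len__(self) -> int:
        return len(self.residue_index)

    @property
    def n_residues(self) -> int:
        return len(self)

    def domain_mask(self, name: str) -> np.ndarray:
        if self.domain_label is None:
            raise ValueError("chain has no domain labels; call assign_domains first")
        return np.asarray([lab == name for lab in self.domain_label])

    def domain_com(self, name: str) -> np.ndarray:
        """Center of mass of a domain (uniform bead masses)."""
        return self.coords[self.domain_mask(name)].mean(axis=0)

    def validate_geometry(self, lo: float = 2.8, hi: float = 4.5) -> None:
        """Check that consecutive Calpha distances are within [lo, hi] angstrom."""
        b = geometry.bond_lengths(self.coords)
        bad = np.where((b < lo) | (b > hi))[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"consecutive Calpha distance {b[i]:.2f} A between residues "
                f"{self.residue_index[i]} and {self.residue_index[i + 1]} is outside "
                f"[{lo}, {hi}] A"
            )


@dataclass
class ContactSet:
    """Native contacts: residue-index pairs with reference distances and strengths."""

    pairs: np.ndarray  # (m, 2) int, 1-based residue indices, I < J
    r0: np.ndarray  # (m,) reference distances, angstrom
    eps: np.ndarray  # (m,) strengths, kcal/mol
    subsystem_tag: np.ndarray  # (m,) str tags (owning energy term)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.r0 = np.asarray(self.r0, dtype=np.float64)
        self.eps = np.asarray(self.eps, dtype=np.float64)
        self.subsystem_tag = np.asarray(self.subsystem_tag, dtype=object)
        m = len(self.pairs)
        if not (len(self.r0) == len(self.eps) == len(self.subsystem_tag) == m):
            raise ValueError("field lengths are inconsistent")
        if m:
            if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
                raise ValueError("contact pairs must satisfy I < J")
            if np.any(self.r0 <= 0):
                raise ValueError("reference distances must be positive")

    def __len__(self) -> int:
        return len(self.pairs)

    def select(self, mask: np.ndarray) -> "ContactSet":
        return ContactSet(self.pairs[mask], self.r0[mask], self.eps[mask], self.subsystem_tag[mask])

    @staticmethod
    def empty() -> "ContactSet":
        return ContactSet(
            np.empty((0, 2), dtype=np.int64),
            np.empty(0),
            np.empty(0),
            np.empty(0, dtype=object),
        )


@dataclass
class ReferenceConformation:
    """A reference state: beads plus native internal coordinates and contacts."""

    name: str  # "open" or "closed"
    beads: BeadChain
    b0: np.ndarray = field(default=None)  # (n-1,) native bond lengths
    theta0: np.ndarray = field(default=None)  # (n-2,) native angles
    phi0: np.ndarray = field(default=None)  # (n-3,) native dihedrals
    contacts: ContactSet = field(default=None)

    def __post_init__(self) -> None:
        coords = self.beads.coords
        if self.b0 is None:
            self.b0 = geometry.bond_lengths(coords)
        if self.theta0 is None:
            self.theta0 = geometry.bond_angles(coords)
        if self.phi0 is None:
            self.phi0 = geometry.dihedral_angles(coords)
        if self.contacts is None:
            self.contacts = ContactSet.empty()

    @property
    def n_residues(self) -> int:
        return self.beads.n_residues


def load_calpha_model(
    pdb_text: str,
    chain_id: str = "A",
    icode_remap: Mapping[tuple[int, str], int] | None = None,
) -> BeadChain:
    """Read one bead per residue (the Calpha atom) from PDB-format text.

    Alternate locations are resolved by highest occupancy, first-listed on
    ties. Residues with insertion codes are rejected unless ``icode_remap``
    maps ``(resseq, icode)`` to a replacement residue number. A residue that
    contains atoms but no Calpha is a hard error naming the residue.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", io.StringIO(pdb_text))
    try:
        model = next(structure.get_models())
    except StopIteration:  # pragma: no cover - malformed input
        raise ValueError("PDB text contains no model")
    if chain_id not in [c.id for c in model]:
        raise ValueError(f"chain {chain_id!r} not found in PDB text")
    chain = model[chain_id]

    indices: list[int] = []
    names: list[str] = []
    coords: list[np.ndarray] = []
    for res in chain:
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue  # heteroatoms (waters, ligands) are not part of the chain
        if icode.strip():
            if icode_remap is None or (resseq, icode) not in icode_remap:
                raise ValueError(
                    f"residue {resseq}{icode} has an insertion code; supply icode_remap"
                )
            resseq = icode_remap[(resseq, icode)]
        if "CA" not in res:
            raise ValueError(f"residue {res.resname} {resseq} has no Calpha atom")
        atom = res["CA"]
        if atom.is_disordered():
            alts = sorted(
                atom.disordered_get_list(),
                key=lambda a: -(a.get_occupancy() or 0.0),
            )
            atom = alts[0]
        indices.append(int(resseq))
        names.append(res.resname)
        coords.append(np.asarray(atom.get_coord(), dtype=np.float64))

    if not indices:
        raise ValueError(f"chain {chain_id!r} contains no polymer residues")
    order = np.argsort(indices, kind="stable")
    indices = [indices[i] for i in order]
    if len(set(indices)) != len(indices):
        raise ValueError("duplicate residue numbers in chain")
    arr_idx = np.asarray(indices)
    if not np.all(np.diff(arr_idx) == 1):
        gap = int(np.where(np.diff(arr_idx) != 1)[0][0])
        raise ValueError(
            f"residue numbering is not contiguous between {arr_idx[gap]} and {arr_idx[gap + 1]}"
        )
    return BeadChain(
        residue_index=arr_idx,
        residue_name=[names[i] for i in order],
        coords=np.asarray([coords[i] for i in order]),
    )


def write_calpha_pdb(chain: BeadChain, chain_id: str = "A") -> str:
    """Serialize a bead chain as CA-only PDB text (for visualization/round-trip)."""
    lines = []
    for k in range(chain.n_residues):
        x, y, z = chain.coords[k]
        name = str(chain.residue_name[k])[:3].ljust(3)
        lines.append(
            f"ATOM  {k + 1:5d}  CA  {name} {chain_id}{chain.residue_index[k]:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append(f"TER   {chain.n_residues + 1:5d}      {str(chain.residue_name[-1])[:3].ljust(3)} "
                 f"{chain_id}{chain.residue_index[-1]:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def assign_domains(
    chain: BeadChain,
    ranges: Mapping[str, Iterable[tuple[int, int]]],
) -> BeadChain:
    """Label every bead with a domain name from closed residue intervals.

    The intervals must be disjoint and jointly cover every residue.
    """
    labels = np.empty(chain.n_residues, dtype=object)
    labels[:] = None
    idx = chain.residue_index
    for name, intervals in ranges.items():
        for lo, hi in intervals:
            mask = (idx >= lo) & (idx <= hi)
            if np.any([labels[i] is not None for i in np.where(mask)[0]]):
                raise ValueError(f"domain interval ({lo}, {hi}) of {name!r} overlaps another domain")
            labels[mask] = name
    uncovered = np.where([lab is None for lab in labels])[0]
    if uncovered.size:
        raise ValueError(
            f"domain ranges do not cover residue {idx[uncovered[0]]} "
            f"({uncovered.size} residues uncovered)"
        )
    return replace(chain, domain_label=labels)


def detect_native_contacts(
    ref: "ReferenceConformation | BeadChain",
    cutoff: float = 8.0,
    min_seq_sep: int = 4,
    eps: float = 1.0,
) -> ContactSet:
    """Native contacts: pairs with |I-J| > min_seq_sep and CA-CA distance <= cutoff.

    Reference distances are the distances in the supplied conformation; each
    pair is stored once with I < J. Strengths are uniform (``eps``) and the
    subsystem tag is left empty for the model builder to fill.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    chain = ref.beads if isinstance(ref, ReferenceConformation) else ref
    coords = chain.coords
    idx = chain.residue_index
    n = len(coords)
    # O(n^2) pair scan, vectorized; n is a few hundred.
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    ii, jj = np.triu_indices(n, k=min_seq_sep + 1)
    keep = d[ii, jj] <= cutoff
    ii, jj = ii[keep], jj[keep]
    pairs = np.stack([idx[ii], idx[jj]], axis=1)
    r0 = d[ii, jj]
    return ContactSet(
        pairs=pairs,
        r0=r0,
        eps=np.full(len(pairs), float(eps)),
        subsystem_tag=np.asarray([""] * len(pairs), dtype=object),
    )


def make_reference(
    name: str,
    chain: BeadChain,
    contact_cutoff: float = 8.0,
    min_seq_sep: int = 4,
) -> ReferenceConformation:
    """Build a reference conformation (native geometry + contacts) from a chain."""
    ref = ReferenceConformation(name=name, beads=chain)
    ref.contacts = detect_native_contacts(ref, cutoff=contact_cutoff, min_seq_sep=min_seq_sep)
    return ref
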