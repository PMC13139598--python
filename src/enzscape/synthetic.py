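"""Synthetic two-state test structures.

Real two-conformation crystal pairs are not always available (or desirable in
tests), so this module generates fully synthetic open/closed reference pairs:

* :func:`make_toy_two_state` -- a small three-domain chain (>= 8 residues)
  whose closed form folds two terminal arms against a central core; the
  open/closed LID-CORE center-of-mass distance differs by a prescribed
  displacement.
* :func:`make_adk_like_two_state` -- a 214-residue, three-domain helix-bundle
  enzyme mimicking the architecture of adenylate kinase (CORE body, two
  hinged arms named LID and NMP, with the standard residue partition
  CORE = 1-29 u 68-117 u 161-214, NMP = 30-67, LID = 118-160). The closed
  form tips both arms over the core so that LID-CORE, NMP-CORE and LID-NMP
  interface contacts form. This is a synthetic stand-in for the 4AKE/1AKE
  crystal pair, not a model of the real protein's coordinates.

Both generators are deterministic (the toy takes an explicit seed for its
small coordinate jitter) and both conformations of a pair share bond lengths
exactly (arms move by rigid hinge rotations).
"""
from __future__ import annotations

import numpy as np

from .structure import (
    ADK_DOMAIN_RANGES,
    BeadChain,
    ReferenceConformation,
    assign_domains,
    make_reference,
)

__all__ = ["make_toy_two_state", "make_adk_like_two_state", "toy_domain_ranges"]

# Calpha helix parameters: consecutive-bead distance ~3.83 A.
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(100.0)

# Frozen arm tip angles (deg) of the 214-residue synthetic enzyme, chosen
# once so that the closed form is clash-free and forms LID-CORE, NMP-CORE
# and LID-NMP interface contacts, while the open form keeps a light
# arm-core interface of its own (anchoring the open basin instead of
# leaving the arms as free rods). See docs/methods.md.
_ADK_TIP_LID = -50.0
_ADK_TIP_NMP = -82.0
_ADK_TIP_LID_OPEN = -25.0
_ADK_TIP_NMP_OPEN = -30.0


def _helix(n: int, center_xy: tuple[float, float], z0: float, direction: int,
           phase: float = 0.0) -> np.ndarray:
    """n beads of a vertical helix at column ``center_xy`` starting at height z0."""
    k = np.arange(n)
    z = z0 + direction * _HELIX_RISE * k
    ang = phase + direction * _HELIX_TWIST * k
    x = center_xy[0] + _HELIX_RADIUS * np.cos(ang)
    y = center_xy[1] + _HELIX_RADIUS * np.sin(ang)
    return np.stack([x, y, z], axis=1)


def _turn(p_from: np.ndarray, p_to: np.ndarray, n: int, bulge: np.ndarray) -> np.ndarray:
    """n interior beads connecting two points along a quadratic Bezier arc.

    ``bulge`` sets the direction in which the turn clears the structure; its
    magnitude is scaled automatically so consecutive beads (including the
    bonds to the flanking points) are 3.0-4.2 A apart.
    """
    chord = p_to - p_from
    c = np.linalg.norm(chord)
    if c < 1e-9:
        raise ValueError("turn endpoints coincide")
    # sagitta direction perpendicular to the chord
    d = bulge - (bulge @ chord) / c**2 * chord
    dn = np.linalg.norm(d)
    if dn < 1e-9:  # bulge parallel to chord: pick any perpendicular
        d = np.cross(chord, np.array([1.0, 0.3, 0.1]))
        dn = np.linalg.norm(d)
    d /= dn

    def arc(h):
        """Circular arc of sagitta h: n interior points, uniform chords."""
        if h < 1e-6:
            t = np.linspace(0.0, 1.0, n + 2)[1:-1, None]
            return p_from + t * chord, c / (n + 1)
        radius = c**2 / (8.0 * h) + h / 2.0
        mid = 0.5 * (p_from + p_to)
        center = mid - d * (radius - h)
        alpha = np.arctan2(c / 2.0, radius - h)  # > pi/2 for major arcs
        # unit vectors spanning the arc plane, from the center
        e1 = (mid + d * h - center) / radius
        e2 = chord / c
        angles = np.linspace(-alpha, alpha, n + 2)[1:-1]
        pts = center + radius * (np.cos(angles)[:, None] * e1 + np.sin(angles)[:, None] * e2)
        step = 2.0 * radius * np.sin(alpha / (n + 1))
        return pts, step

    pts, step = arc(0.0)
    if step > 4.4:
        raise ValueError(f"points {c:.1f} A apart are too far for {n} turn beads")
    if step >= 3.0:
        # bend "comfortable" turns so no bead triple is close to collinear
        # (near-collinear geometry makes dihedral gradients ill-conditioned);
        # grow the sagitta as far as the bond-length ceiling allows
        h_try = 0.25 * c
        while h_try > 0.5:
            pts2, step2 = arc(h_try)
            if step2 <= 4.35:
                pts = pts2
                break
            h_try *= 0.8
    if step < 3.0:  # straight line too short per bead: grow the sagitta
        lo_h, hi_h = 0.0, 2.0 * c
        for _ in range(100):
            hm = 0.5 * (lo_h + hi_h)
            pts, step = arc(hm)
            if 3.0 <= step <= 4.2:
                break
            if step < 3.0:
                lo_h = hm
            else:
                hi_h = hm
        else:
            raise ValueError(
                f"cannot connect points {c:.1f} A apart with {n} turn beads"
            )
    return pts


def _rotate_about_axis(points: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                       angle: float) -> np.ndarray:
    """Rigid rotation of points about the axis through p0 and p1 (Rodrigues)."""
    axis = p1 - p0
    nrm = np.linalg.norm(axis)
    if nrm < 1e-12:
        raise ValueError("degenerate hinge axis")
    k = axis / nrm
    v = points - p0
    c, s = np.cos(angle), np.sin(angle)
    rotated = v * c + np.cross(k, v) * s + np.outer(v @ k, k) * (1 - c)
    return rotated + p0


def _build_adk_like_open() -> np.ndarray:
    """Open conformation: helix-bundle core with both arm towers standing."""
    coords: list[np.ndarray] = []
    up, dn = +1, -1
    # Column layout (10 A spacing). The NMP tower (above columns B/C, wall in
    # the y in [-10, 0] plane pair) tips steeply toward +x and lies over the
    # D/E core columns; the LID tower (above F/G, wall at y in [10, 20])
    # reclines toward -x above the H/I core columns and the lying NMP. The
    # two walls never share a y plane, so the folded arms cannot collide.
    A, B = (-10.0, 0.0), (0.0, 0.0)
    C, D, E = (0.0, -10.0), (10.0, -10.0), (20.0, -10.0)
    F, G = (20.0, 10.0), (20.0, 20.0)
    H, I, J = (10.0, 20.0), (0.0, 20.0), (-10.0, 20.0)

    plan = [
        ("helix", A, 18.0, dn, 13),   # res 1-13   core segment 1
        ("turn", 3, np.array([0.0, 0.0, -4.0])),
        ("helix", B, 2.0, up, 30),    # res 17-46  core seg 1 end + NMP tower up
        ("turn", 3, np.array([0.0, 0.0, 4.0])),
        ("helix", C, 45.5, dn, 29, (29, 17)),  # res 50-78 NMP tower down + core seg 2
        ("turn", 2, np.array([0.0, 0.0, -4.0])),
        ("helix", D, 0.0, up, 13),    # res 81-93
        ("turn", 2, np.array([0.0, -4.0, 1.5])),
        ("helix", E, 18.0, dn, 10),   # res 96-105
        ("turn", 4, np.array([-2.0, 0.0, -2.0])),  # res 106-109 bridge to the LID wall
        ("helix", F, 6.0, up, 27),    # res 110-136 core seg 2 end + LID tower up
        ("turn", 3, np.array([0.0, 0.0, 4.0])),
        ("helix", G, 48.0, dn, 29, (117, 20)),  # res 140-168 LID tower down + core seg 3
        ("turn", 2, np.array([0.0, 0.0, -4.0])),
        ("helix", H, 0.0, up, 13),    # res 171-183
        ("turn", 2, np.array([0.0, 4.0, 1.5])),
        ("helix", I, 16.5, dn, 13),   # res 186-198
        ("turn", 2, np.array([0.0, 0.0, -4.0])),
        ("helix", J, 0.0, up, 14),    # res 201-214
    ]
    i = 0
    pending_turn = None
    while i < len(plan):
        item = plan[i]
        if item[0] == "helix":
            _, col, z0, direction, n = item[:5]
            hinge = item[5] if len(item) > 5 else None
            if not coords:
                coords.append(_helix(n, col, z0, direction))
            else:
                prev_end = coords[-1][-1]
                if hinge is not None:
                    # pin the phase so the bead at local index k shares its x
                    # coordinate with a previously built hinge-partner bead,
                    # making the closed-form hinge axis run cleanly along y
                    anchor_global, k = hinge
                    built = np.concatenate(coords, axis=0)
                    target = np.clip(
                        (built[anchor_global, 0] - col[0]) / _HELIX_RADIUS, -1.0, 1.0
                    )
                    cands = [np.arccos(target), -np.arccos(target)]
                    phases = [a - direction * _HELIX_TWIST * k for a in cands]
                else:
                    # pick the helix phase that brings its first bead closest
                    # to the previous helix end, so the turn arc stays short
                    phases = np.linspace(0.0, 2 * np.pi, 24, endpoint=False)
                best = min(
                    phases,
                    key=lambda ph: np.linalg.norm(_helix(1, col, z0, direction, ph)[0] - prev_end),
                )
                h = _helix(n, col, z0, direction, best)
                tn, bulge = pending_turn
                coords.append(_turn(prev_end, h[0], tn, bulge))
                coords.append(h)
                pending_turn = None
        else:
            _, n, bulge = item
            pending_turn = (n, bulge)
        i += 1
    xyz = np.concatenate(coords, axis=0)
    assert xyz.shape == (214, 3)
    return xyz


def make_adk_like_two_state(
    contact_cutoff: float = 8.0,
    min_seq_sep: int = 4,
    tip_lid: float = _ADK_TIP_LID,
    tip_nmp: float = _ADK_TIP_NMP,
    tip_lid_open: float = _ADK_TIP_LID_OPEN,
    tip_nmp_open: float = _ADK_TIP_NMP_OPEN,
) -> tuple[ReferenceConformation, ReferenceConformation]:
    """Synthetic 214-residue three-domain enzyme in open and closed forms.

    Returns ``(open_ref, closed_ref)`` with domain labels assigned from the
    standard CORE/NMP/LID partition and native contacts detected per
    conformation. Deterministic.
    """
    base = _build_adk_like_open()

    # hinge beads (0-based): NMP interior = 31..66 rotates about res 30/67;
    # LID interior = 119..159 rotates about res 118/160. Both conformations
    # are rigid arm rotations of the same base, so they share bond lengths.
    nmp_sel = slice(30, 66)   # beads between hinge residues 30 and 67 (1-based)
    lid_sel = slice(118, 159)

    def _tipped(angle_lid, angle_nmp):
        xyz = base.copy()
        xyz[nmp_sel] = _rotate_about_axis(
            xyz[nmp_sel], base[29], base[66], np.deg2rad(angle_nmp)
        )
        xyz[lid_sel] = _rotate_about_axis(
            xyz[lid_sel], base[117], base[159], np.deg2rad(angle_lid)
        )
        return xyz

    xyz_open = _tipped(tip_lid_open, tip_nmp_open)
    xyz_closed = _tipped(tip_lid, tip_nmp)

    refs = []
    for name, xyz in (("open", xyz_open), ("closed", xyz_closed)):
        chain = BeadChain(
            residue_index=np.arange(1, 215),
            residue_name=np.asarray(["ALA"] * 214, dtype=object),
            coords=xyz,
        )
        chain = assign_domains(chain, ADK_DOMAIN_RANGES)
        chain.validate_geometry()
        refs.append(make_reference(name, chain, contact_cutoff, min_seq_sep))
    return refs[0], refs[1]


def toy_domain_ranges(n_residues: int) -> dict[str, tuple[tuple[int, int], ...]]:
    """Domain partition of the toy chain: NMP arm, central CORE, LID arm."""
    n_nmp = max(2, int(round(0.3 * n_residues)))
    n_lid = max(2, int(round(0.3 * n_residues)))
    return {
        "NMP": ((1, n_nmp),),
        "CORE": ((n_nmp + 1, n_residues - n_lid),),
        "LID": ((n_residues - n_lid + 1, n_residues),),
    }


def make_toy_two_state(
    n_residues: int,
    displacement: float,
    seed: int,
    contact_cutoff: float = 8.0,
    min_seq_sep: int = 4,
) -> tuple[ReferenceConformation, ReferenceConformation]:
    """Small synthetic two-state chain with a prescribed open/closed gap.

    The open form is a gently jittered, nearly straight chain; the closed
    form folds the terminal LID and NMP arms toward the core by rigid hinge
    rotations, reducing the LID-CORE center-of-mass distance by exactly
    ``displacement`` (and the NMP-CORE distance by half of it). Deterministic
    for a given seed; ``displacement = 0`` returns identical conformations.
    """
    if n_residues < 8:
        raise ValueError("toy two-state chain needs at least 8 residues")
    if displacement < 0:
        raise ValueError("displacement must be non-negative")
    rng = np.random.default_rng(seed)
    ranges = toy_domain_ranges(n_residues)
    n_nmp = ranges["NMP"][0][1]
    lid_lo = ranges["LID"][0][0]

    # base chain along x: a zig-zag (alternating y offsets) keeps every bead
    # triple well away from collinearity, plus bounded random jitter
    xyz = np.zeros((n_residues, 3))
    xyz[:, 0] = 3.8 * np.arange(n_residues)
    xyz[:, 1] = 0.9 * (np.arange(n_residues) % 2)
    xyz[:, 1:] += np.clip(rng.normal(0.0, 0.15, size=(n_residues, 2)), -0.4, 0.4)

    # The fold axis lies in the chain plane, tilted 80 deg from the chain
    # direction: a 180 deg rotation then lays an arm back alongside the core
    # at a ~20 deg splay, close enough to form interface contacts. LID folds
    # to the +y side, NMP (pointing the other way) to -y, so the folded arms
    # do not collide.
    axis_dir = np.array([np.cos(np.deg2rad(80.0)), np.sin(np.deg2rad(80.0)), 0.0])

    def fold(coords, arm_idx, hinge_idx, angle):
        """Rotate arm beads about the tilted in-plane axis through the hinge bead."""
        p0 = coords[hinge_idx]
        return _rotate_about_axis(coords[arm_idx], p0, p0 + axis_dir, angle)

    lid_arm = np.arange(lid_lo - 1, n_residues)  # 0-based, rotate whole arm incl. none fixed
    nmp_arm = np.arange(0, n_nmp)
    lid_hinge = lid_lo - 2  # last CORE bead
    nmp_hinge = n_nmp  # first CORE bead

    core_mask = np.zeros(n_residues, bool)
    core_mask[n_nmp:lid_lo - 1] = True

    def lid_com_distance(coords):
        return np.linalg.norm(coords[lid_arm].mean(0) - coords[core_mask].mean(0))

    def nmp_com_distance(coords):
        return np.linalg.norm(coords[nmp_arm].mean(0) - coords[core_mask].mean(0))

    def folded(angle_lid, angle_nmp):
        out = xyz.copy()
        out[lid_arm] = fold(xyz, lid_arm, lid_hinge, angle_lid)
        out[nmp_arm] = fold(xyz, nmp_arm, nmp_hinge, angle_nmp)
        return out

    def solve_angle(target_reduction, which):
        if target_reduction <= 0:
            return 0.0
        ref = lid_com_distance(xyz) if which == "lid" else nmp_com_distance(xyz)
        lo, hi = 0.0, np.deg2rad(180.0)
        metric = lid_com_distance if which == "lid" else nmp_com_distance

        def reduction(a):
            c = folded(a, 0.0) if which == "lid" else folded(0.0, a)
            return ref - metric(c)

        max_red = reduction(hi)
        if target_reduction > max_red:
            raise ValueError(
                f"displacement {target_reduction:.1f} A exceeds the maximum achievable "
                f"{max_red:.1f} A for this chain length"
            )
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if reduction(mid) < target_reduction:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    a_lid = solve_angle(displacement, "lid")
    a_nmp = solve_angle(displacement / 2.0, "nmp")
    xyz_closed = folded(a_lid, a_nmp)

    refs = []
    for name, coords in (("open", xyz), ("closed", xyz_closed)):
        chain = BeadChain(
            residue_index=np.arange(1, n_residues + 1),
            residue_name=np.asarray(["GLY"] * n_residues, dtype=object),
            coords=coords,
        )
        chain = assign_domains(chain, ranges)
        chain.validate_geometry()
        refs.append(make_reference(name, chain, contact_cutoff, min_seq_sep))
    return refs[0], refs[1]
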