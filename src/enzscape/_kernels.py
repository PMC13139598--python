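"""Compiled (numba) simulation engine.

The reference NumPy implementations in :mod:`enzscape.energy`,
:mod:`enzscape.multibasin` and :mod:`enzscape.ligand` define the model;
this module evaluates the identical functional forms inside a single
jitted loop for production-scale trajectories. Consistency between the two
paths is asserted by the test suite.

Implementation notes, all exact or accurate to ~1e-8 so the two paths agree
far below thermal noise:

* forces are split multiple-time-step style: stiff harmonic bonds are
  integrated every step, all smooth terms (angle/dihedral Gaussians,
  contacts, excluded volume, ligand restraints, crowders, walls) enter as
  impulse kicks every ``respa`` steps (r-RESPA within BAOAB);
* arccos uses an Abramowitz-Stegun style polynomial, the wrapped dihedral
  difference is obtained from cos/sin decomposition against precomputed
  native cos/sin (no atan2), and Gaussians use a table-assisted
  polynomial exp — all branch-free so hot loops vectorize;
* random numbers come from an internal xoshiro256** generator with a
  ziggurat Gaussian sampler, so runs are bit-reproducible for a given seed
  independent of NumPy versions.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------- RNG -----


def _zig_tables():
    """Marsaglia-Tsang 128-layer ziggurat tables for the standard normal."""
    m1 = 2147483648.0
    dn = 3.442619855899
    tn = dn
    vn = 9.91256303526217e-3
    kn = np.zeros(128, dtype=np.int64)
    wn = np.zeros(128)
    fn = np.zeros(128)
    q = vn / math.exp(-0.5 * dn * dn)
    kn[0] = int(dn / q * m1)
    kn[1] = 0
    wn[0] = q / m1
    wn[127] = dn / m1
    fn[0] = 1.0
    fn[127] = math.exp(-0.5 * dn * dn)
    for i in range(126, 0, -1):
        dn = math.sqrt(-2.0 * math.log(vn / dn + math.exp(-0.5 * dn * dn)))
        kn[i + 1] = int(dn / tn * m1)
        tn = dn
        fn[i] = math.exp(-0.5 * dn * dn)
        wn[i] = dn / m1
    return kn, wn, fn


_ZIG_KN, _ZIG_WN, _ZIG_FN = _zig_tables()
_ZIG_R = 3.442619855899


@njit(cache=True, fastmath=True, inline="always")
def _rotl(x, k):
    return ((x << k) | (x >> (np.uint64(64) - k))) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True)
def rng_seed(seed):
    """Initialize xoshiro256** state from a 64-bit seed (splitmix64)."""
    state = np.empty(4, dtype=np.uint64)
    z = np.uint64(seed)
    for i in range(4):
        z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        t = z
        t = ((t ^ (t >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        t = ((t ^ (t >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
        state[i] = t ^ (t >> np.uint64(31))
    return state


@njit(cache=True, fastmath=True, inline="always")
def rng_u64(state):
    s1 = state[1]
    result = (_rotl((s1 * np.uint64(5)) & np.uint64(0xFFFFFFFFFFFFFFFF), np.uint64(7))
              * np.uint64(9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    t = (s1 << np.uint64(17)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    state[2] ^= state[0]
    state[3] ^= s1
    state[1] ^= state[2]
    state[0] ^= state[3]
    state[2] ^= t
    state[3] = _rotl(state[3], np.uint64(45))
    return result


@njit(cache=True, fastmath=True, inline="always")
def rng_uniform(state):
    """Uniform double in [0, 1)."""
    return (rng_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, fastmath=True, inline="always")
def rng_normal(state):
    """Standard normal via the 128-layer ziggurat."""
    while True:
        u = rng_u64(state)
        hz = np.int32(u & np.uint64(0xFFFFFFFF))
        iz = np.int64(hz & np.int32(127))
        ahz = np.int64(hz)
        if ahz < 0:
            ahz = -ahz
        if ahz < _ZIG_KN[iz]:
            return np.float64(hz) * _ZIG_WN[iz]
        if iz == 0:
            while True:
                x = -math.log(rng_uniform(state) + 1e-300) / _ZIG_R
                y = -math.log(rng_uniform(state) + 1e-300)
                if y + y >= x * x:
                    if hz > 0:
                        return _ZIG_R + x
                    return -(_ZIG_R + x)
        else:
            x = np.float64(hz) * _ZIG_WN[iz]
            if _ZIG_FN[iz] + rng_uniform(state) * (_ZIG_FN[iz - 1] - _ZIG_FN[iz]) < math.exp(-0.5 * x * x):
                return x


# ------------------------------------------------ fast special functions --

_LOG2E = 1.4426950408889634
_EXPC = np.array([math.log(2.0) ** k / math.factorial(k) for k in range(8)])
_POW2 = np.array([2.0**k for k in range(-130, 2)])  # index k+130


@njit(cache=True, fastmath=True, inline="always")
def fexp(x):
    """exp(x) for x in [-85, 0]: 2^n * 2^f, degree-7 Taylor on f in [-0.5, 0.5].

    Branch-free (the 2^n factor is a table lookup; input is clamped), with
    relative error < 1e-8.
    """
    x = max(x, -85.0)
    t = x * _LOG2E
    n = int(np.floor(t + 0.5))
    f = t - n
    p = _EXPC[7]
    p = p * f + _EXPC[6]
    p = p * f + _EXPC[5]
    p = p * f + _EXPC[4]
    p = p * f + _EXPC[3]
    p = p * f + _EXPC[2]
    p = p * f + _EXPC[1]
    p = p * f + _EXPC[0]
    return p * _POW2[n + 130]


@njit(cache=True, fastmath=True, inline="always")
def facos(x):
    """arccos on [-1, 1] via sqrt(1-|x|) * poly(|x|), mirrored; |err| ~ 2e-8."""
    ax = min(abs(x), 1.0)
    p = -0.0012624911
    p = p * ax + 0.0066700901
    p = p * ax - 0.0170881256
    p = p * ax + 0.0308918810
    p = p * ax - 0.0501743046
    p = p * ax + 0.0889789874
    p = p * ax - 0.2145988016
    p = p * ax + 1.5707963050
    t = math.sqrt(1.0 - ax) * p
    neg = 0.5 - 0.5 * np.copysign(1.0, x)  # 1 if x < 0 else 0
    return t + neg * (np.pi - 2.0 * t)


@njit(cache=True, fastmath=True, inline="always")
def _wrapped_delta(cph, sph, c0, s0):
    """wrap(phi - phi0) from cos/sin of phi and phi0, in (-pi, pi]."""
    cd = cph * c0 + sph * s0
    sd = sph * c0 - cph * s0
    return np.copysign(facos(cd), sd)


# ------------------------------------------------------------- lists ------


@njit(cache=True, fastmath=True)
def rebuild_exv_list(pos, excl, cutoff2, pairs_out):
    """Protein excluded-volume neighbor list from the exclusion matrix."""
    n = pos.shape[0]
    m = 0
    for i in range(n):
        for j in range(i + 5, n):
            if excl[i, j]:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < cutoff2:
                if m >= pairs_out.shape[0]:
                    raise RuntimeError("neighbor-list buffer overflow")
                pairs_out[m, 0] = i
                pairs_out[m, 1] = j
                m += 1
    return m


@njit(cache=True, fastmath=True)
def rebuild_cross_list(pos_a, pos_b, cutoff2, pairs_out):
    na, nb = pos_a.shape[0], pos_b.shape[0]
    m = 0
    for i in range(na):
        for j in range(nb):
            dx = pos_b[j, 0] - pos_a[i, 0]
            dy = pos_b[j, 1] - pos_a[i, 1]
            dz = pos_b[j, 2] - pos_a[i, 2]
            if dx * dx + dy * dy + dz * dz < cutoff2:
                if m >= pairs_out.shape[0]:
                    raise RuntimeError("neighbor-list buffer overflow")
                pairs_out[m, 0] = i
                pairs_out[m, 1] = j
                m += 1
    return m


@njit(cache=True, fastmath=True)
def rebuild_self_list(pos, cutoff2, pairs_out):
    n = pos.shape[0]
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            if dx * dx + dy * dy + dz * dz < cutoff2:
                if m >= pairs_out.shape[0]:
                    raise RuntimeError("neighbor-list buffer overflow")
                pairs_out[m, 0] = i
                pairs_out[m, 1] = j
                m += 1
    return m


@njit(cache=True, fastmath=True, inline="always")
def _wall(d, K, sig):
    """Three-branch wall: energy and outward force magnitude."""
    if d > 3.0 * sig:
        return 0.0, 0.0
    if d >= 0.8 * sig:
        t = sig / d
        t2 = t * t
        t4 = t2 * t2
        t12 = t4 * t4 * t4
        e = K * t12
        return e, 12.0 * e / d
    amp = K * 1.25**12
    e = amp * (1.0 + 12.0 * (0.8 * sig - d) / (0.8 * sig))
    return e, amp * 12.0 / (0.8 * sig)


# ------------------------------------------------------------- forces -----


@njit(cache=True, fastmath=True)
def compute_bond_forces(pos, F, b0s, bond_owner, w_open, k_bond):
    """Add harmonic bond forces (the fastest time-step class)."""
    n = pos.shape[0]
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        b = math.sqrt(dx * dx + dy * dy + dz * dz)
        own = bond_owner[i]
        w1 = w_open[own]
        pref = 2.0 * k_bond * (
            w1 * (b - b0s[i, 0]) + (1.0 - w1) * (b - b0s[i, 1])
        ) / b
        fx = pref * dx
        fy = pref * dy
        fz = pref * dz
        F[i, 0] += fx
        F[i, 1] += fy
        F[i, 2] += fz
        F[i + 1, 0] -= fx
        F[i + 1, 1] -= fy
        F[i + 1, 2] -= fz


@njit(cache=True, fastmath=True)
def eval_exv(pos, cpos, exv_pairs, n_exv, pc_pairs, n_pc, pp, F, Fc):
    """Middle time-step class: protein excluded volume and protein-crowder
    repulsion (steep terms that floppy regions can penetrate quickly).
    Overwrites F and Fc."""
    n = pos.shape[0]
    M = cpos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    for i in range(M):
        Fc[i, 0] = 0.0
        Fc[i, 1] = 0.0
        Fc[i, 2] = 0.0
    eps_exv = pp[7]
    sig_exv = pp[8]
    rc_exv = pp[9]
    rc2 = rc_exv * rc_exv
    shift = eps_exv * (sig_exv / rc_exv) ** 12
    sig2 = sig_exv * sig_exv
    e_tot = 0.0
    for k in range(n_exv):
        i = exv_pairs[k, 0]
        j = exv_pairs[k, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        m = 1.0 if r2 < rc2 else 0.0
        t2 = sig2 / r2
        t6 = t2 * t2 * t2
        t12 = t6 * t6
        e = eps_exv * t12 * m
        e_tot += e - shift * m
        pref = 12.0 * e / r2
        F[i, 0] -= pref * dx
        F[i, 1] -= pref * dy
        F[i, 2] -= pref * dz
        F[j, 0] += pref * dx
        F[j, 1] += pref * dy
        F[j, 2] += pref * dz

    eps_pc = pp[12]
    sref = pp[13]
    spc = pp[15]
    eps_attr = pp[16]
    for k in range(n_pc):
        i = pc_pairs[k, 0]
        j = pc_pairs[k, 1]
        dx = cpos[j, 0] - pos[i, 0]
        dy = cpos[j, 1] - pos[i, 1]
        dz = cpos[j, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        x = max(r - spc + sref, 1e-6)
        t = sref / x
        m = 1.0 if t >= 0.4 or eps_attr > 0.0 else 0.0
        t6 = t * t * t
        t6 = t6 * t6
        t12 = t6 * t6
        e = eps_pc * t12 * m
        fmag = 12.0 * e / x
        if eps_attr > 0.0:
            e -= eps_attr * t6 * m
            fmag -= 6.0 * eps_attr * t6 * m / x
        e_tot += e
        pref = fmag / max(r, 1e-6)
        F[i, 0] -= pref * dx
        F[i, 1] -= pref * dy
        F[i, 2] -= pref * dz
        Fc[j, 0] += pref * dx
        Fc[j, 1] += pref * dy
        Fc[j, 2] += pref * dz
    return e_tot


@njit(cache=True, fastmath=True)
def eval_slow(
    pos, cpos, F, Fc,
    bond_owner, b0s, ang_owner, th0s, dih_owner, ph0_cs,
    cont_i, cont_j, cont_r0, cont_eps, cont_owner, cont_basin,
    dV, Delta,
    occ, lig_i, lig_j, lig_r0s, lig_eps, lig_site,
    cc_pairs, n_cc,
    pp, w_open, e_exv,
    bv, ang_store, dih_store, cont_store,
):
    """Smooth terms (outer time-step class): angle/dihedral Gaussians with the
    flexible prior, native contacts, ligand restraints, crowders and walls.

    Bond and excluded-volume ENERGIES enter the double-basin mixing here
    (``e_exv`` is the excluded-volume energy evaluated at the same
    configuration), but their forces belong to the faster classes.
    Overwrites F (protein) and Fc (crowders), refreshes ``w_open`` and
    returns the total potential energy.

    pp layout: [0] k_bond [1] eps_angle [2] eps_dihedral [3] eps_flp
    [4] w_theta [5] w_phi [6] w_c [7] eps_exv [8] sigma_exv [9] exv_cutoff
    [10] sigma_lig [11] eps_cc [12] eps_pc [13] sigma_ref [14] sigma_cc
    [15] sigma_pc [16] eps_attr [17] box_L [18] K_box [19] sigma_wall
    [20] r_star_lid [21] r_star_nmp

    The flexible-local prior is centered on the basin-0 (open) natives.
    """
    n = pos.shape[0]
    M = cpos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    for i in range(M):
        Fc[i, 0] = 0.0
        Fc[i, 1] = 0.0
        Fc[i, 2] = 0.0

    E = np.zeros((4, 2))

    k_bond = pp[0]
    eps_ang = pp[1]
    eps_dih = pp[2]
    eps_flp = pp[3]
    inv_wth2 = 1.0 / (pp[4] * pp[4])
    inv_wph2 = 1.0 / (pp[5] * pp[5])
    inv_wc2 = 1.0 / (pp[6] * pp[6])

    # ---- bond vectors (shared geometry) + bond energies
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        b = math.sqrt(dx * dx + dy * dy + dz * dz)
        bv[i, 0] = dx
        bv[i, 1] = dy
        bv[i, 2] = dz
        bv[i, 3] = b
        own = bond_owner[i]
        db0 = b - b0s[i, 0]
        E[own, 0] += k_bond * db0 * db0
        if own != 0:
            db1 = b - b0s[i, 1]
            E[own, 1] += k_bond * db1 * db1

    # ---- angles
    for i in range(n - 2):
        ux = -bv[i, 0]
        uy = -bv[i, 1]
        uz = -bv[i, 2]
        vx = bv[i + 1, 0]
        vy = bv[i + 1, 1]
        vz = bv[i + 1, 2]
        nu = bv[i, 3]
        nv = bv[i + 1, 3]
        nunv = nu * nv
        h = (ux * vx + uy * vy + uz * vz) / nunv
        h = min(max(h, -1.0), 1.0)
        th = facos(h)
        s = math.sqrt(1.0 - h * h)
        s = max(s, 0.05)  # cap the geometric gradient near collinearity
        inv = -1.0 / s
        c1 = inv / nunv
        c2 = inv * h / (nu * nu)
        c3 = inv * h / (nv * nv)
        ang_store[i, 0] = c1 * vx - c2 * ux
        ang_store[i, 1] = c1 * vy - c2 * uy
        ang_store[i, 2] = c1 * vz - c2 * uz
        ang_store[i, 3] = c1 * ux - c3 * vx
        ang_store[i, 4] = c1 * uy - c3 * vy
        ang_store[i, 5] = c1 * uz - c3 * vz
        d0 = th - th0s[i, 0]
        d1 = th - th0s[i, 1]
        g0 = fexp(-0.5 * d0 * d0 * inv_wth2)
        g1 = fexp(-0.5 * d1 * d1 * inv_wth2)
        gf = fexp(-0.125 * d0 * d0 * inv_wth2)
        ang_store[i, 6] = eps_ang * g0 * d0 * inv_wth2
        ang_store[i, 7] = eps_ang * g1 * d1 * inv_wth2
        ang_store[i, 8] = 0.25 * eps_flp * gf * d0 * inv_wth2
        ang_store[i, 9] = g0
        ang_store[i, 10] = g1
        ang_store[i, 11] = gf

    for i in range(n - 2):
        own = ang_owner[i]
        E[own, 0] += -eps_ang * ang_store[i, 9]
        if own != 0:
            E[own, 1] += -eps_ang * ang_store[i, 10]
        E[0, 0] += -eps_flp * ang_store[i, 11]

    # ---- dihedrals
    for i in range(n - 3):
        b1x = bv[i, 0]
        b1y = bv[i, 1]
        b1z = bv[i, 2]
        b2x = bv[i + 1, 0]
        b2y = bv[i + 1, 1]
        b2z = bv[i + 1, 2]
        b3x = bv[i + 2, 0]
        b3y = bv[i + 2, 1]
        b3z = bv[i + 2, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        nb2 = bv[i + 1, 3]
        b2sq = nb2 * nb2
        mx = n1y * b2z - n1z * b2y
        my = n1z * b2x - n1x * b2z
        mz = n1x * b2y - n1y * b2x
        xx = n1x * n2x + n1y * n2y + n1z * n2z
        yy = (mx * n2x + my * n2y + mz * n2z) / nb2
        hyp = math.sqrt(xx * xx + yy * yy)
        hyp = max(hyp, 1e-12)
        cph = xx / hyp
        sph = yy / hyp
        # floor |b x b|^2: caps the dihedral gradient near collinear triples
        n1sq = max(n1x * n1x + n1y * n1y + n1z * n1z, 2.0)
        n2sq = max(n2x * n2x + n2y * n2y + n2z * n2z, 2.0)
        a0 = nb2 / n1sq
        a3 = -nb2 / n2sq
        dih_store[i, 0] = a0 * n1x
        dih_store[i, 1] = a0 * n1y
        dih_store[i, 2] = a0 * n1z
        dih_store[i, 3] = a3 * n2x
        dih_store[i, 4] = a3 * n2y
        dih_store[i, 5] = a3 * n2z
        dih_store[i, 6] = (b1x * b2x + b1y * b2y + b1z * b2z) / b2sq
        dih_store[i, 7] = (b3x * b2x + b3y * b2y + b3z * b2z) / b2sq
        d0 = _wrapped_delta(cph, sph, ph0_cs[i, 0], ph0_cs[i, 1])
        d1 = _wrapped_delta(cph, sph, ph0_cs[i, 2], ph0_cs[i, 3])
        g0 = fexp(-0.5 * d0 * d0 * inv_wph2)
        g1 = fexp(-0.5 * d1 * d1 * inv_wph2)
        gf = fexp(-0.125 * d0 * d0 * inv_wph2)
        dih_store[i, 8] = eps_dih * g0 * d0 * inv_wph2
        dih_store[i, 9] = eps_dih * g1 * d1 * inv_wph2
        dih_store[i, 10] = 0.25 * eps_flp * gf * d0 * inv_wph2
        dih_store[i, 11] = g0
        dih_store[i, 12] = g1
        dih_store[i, 13] = gf

    for i in range(n - 3):
        own = dih_owner[i]
        E[own, 0] += -eps_dih * dih_store[i, 11]
        if own != 0:
            E[own, 1] += -eps_dih * dih_store[i, 12]
        E[0, 0] += -eps_flp * dih_store[i, 13]

    # ---- contacts
    ncont = cont_i.shape[0]
    for k in range(ncont):
        i = cont_i[k]
        j = cont_j[k]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - cont_r0[k]
        g = fexp(-0.5 * dr * dr * inv_wc2)
        E[cont_owner[k], cont_basin[k]] += -cont_eps[k] * g
        f = cont_eps[k] * g * dr * inv_wc2 / r
        cont_store[k, 0] = f * dx
        cont_store[k, 1] = f * dy
        cont_store[k, 2] = f * dz

    # ---- double-basin mixing (includes the bond and exv energies)
    e_total = E[0, 0] + e_exv
    w_open[0] = 1.0
    for t in range(1, 4):
        v1 = E[t, 0]
        v2 = E[t, 1] + dV[t - 1]
        u = 0.5 * (v1 - v2)
        sq = math.sqrt(u * u + Delta[t - 1] * Delta[t - 1])
        e_total += 0.5 * (v1 + v2) - sq
        if sq == 0.0:
            w_open[t] = 0.5
        else:
            w_open[t] = 0.5 * (1.0 - u / sq)

    # ---- weighted gradient application
    for i in range(n - 2):
        own = ang_owner[i]
        w1 = w_open[own]
        dv = w1 * ang_store[i, 6] + (1.0 - w1) * ang_store[i, 7] + ang_store[i, 8]
        gax = ang_store[i, 0]
        gay = ang_store[i, 1]
        gaz = ang_store[i, 2]
        gcx = ang_store[i, 3]
        gcy = ang_store[i, 4]
        gcz = ang_store[i, 5]
        F[i, 0] -= dv * gax
        F[i, 1] -= dv * gay
        F[i, 2] -= dv * gaz
        F[i + 2, 0] -= dv * gcx
        F[i + 2, 1] -= dv * gcy
        F[i + 2, 2] -= dv * gcz
        F[i + 1, 0] += dv * (gax + gcx)
        F[i + 1, 1] += dv * (gay + gcy)
        F[i + 1, 2] += dv * (gaz + gcz)

    for i in range(n - 3):
        own = dih_owner[i]
        w1 = w_open[own]
        dv = w1 * dih_store[i, 8] + (1.0 - w1) * dih_store[i, 9] + dih_store[i, 10]
        g0x = dih_store[i, 0]
        g0y = dih_store[i, 1]
        g0z = dih_store[i, 2]
        g3x = dih_store[i, 3]
        g3y = dih_store[i, 4]
        g3z = dih_store[i, 5]
        d12 = dih_store[i, 6]
        d32 = dih_store[i, 7]
        g1x = -(1.0 + d12) * g0x + d32 * g3x
        g1y = -(1.0 + d12) * g0y + d32 * g3y
        g1z = -(1.0 + d12) * g0z + d32 * g3z
        g2x = d12 * g0x - (1.0 + d32) * g3x
        g2y = d12 * g0y - (1.0 + d32) * g3y
        g2z = d12 * g0z - (1.0 + d32) * g3z
        F[i, 0] -= dv * g0x
        F[i, 1] -= dv * g0y
        F[i, 2] -= dv * g0z
        F[i + 1, 0] -= dv * g1x
        F[i + 1, 1] -= dv * g1y
        F[i + 1, 2] -= dv * g1z
        F[i + 2, 0] -= dv * g2x
        F[i + 2, 1] -= dv * g2y
        F[i + 2, 2] -= dv * g2z
        F[i + 3, 0] -= dv * g3x
        F[i + 3, 1] -= dv * g3y
        F[i + 3, 2] -= dv * g3z

    for k in range(ncont):
        own = cont_owner[k]
        if own == 0:
            w = 1.0
        elif cont_basin[k] == 0:
            w = w_open[own]
        else:
            w = 1.0 - w_open[own]
        i = cont_i[k]
        j = cont_j[k]
        fx = w * cont_store[k, 0]
        fy = w * cont_store[k, 1]
        fz = w * cont_store[k, 2]
        F[i, 0] += fx
        F[i, 1] += fy
        F[i, 2] += fz
        F[j, 0] -= fx
        F[j, 1] -= fy
        F[j, 2] -= fz

    # ---- ligand terms (active species only)
    sigma_lig = pp[10]
    inv_sl2 = 1.0 / (sigma_lig * sigma_lig)
    nlig = lig_i.shape[0]
    for k in range(nlig):
        sp = occ[lig_site[k]]
        if sp == 0:
            continue
        i = lig_i[k]
        j = lig_j[k]
        r0 = lig_r0s[k, sp - 1]
        eps = lig_eps[k, sp - 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0
        g = fexp(-0.5 * dr * dr * inv_sl2)
        e_total += -eps * g
        f = eps * g * dr * inv_sl2 / r
        F[i, 0] += f * dx
        F[i, 1] += f * dy
        F[i, 2] += f * dz
        F[j, 0] -= f * dx
        F[j, 1] -= f * dy
        F[j, 2] -= f * dz

    # ---- crowder-crowder repulsion
    eps_cc = pp[11]
    sref = pp[13]
    scc = pp[14]
    for k in range(n_cc):
        i = cc_pairs[k, 0]
        j = cc_pairs[k, 1]
        dx = cpos[j, 0] - cpos[i, 0]
        dy = cpos[j, 1] - cpos[i, 1]
        dz = cpos[j, 2] - cpos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        x = max(r - scc + sref, 1e-6)
        t = sref / x
        m = 1.0 if t >= 0.4 else 0.0
        t6 = t * t * t
        t6 = t6 * t6
        t12 = t6 * t6
        e = eps_cc * t12 * m
        e_total += e
        pref = 12.0 * e / x / r
        Fc[i, 0] -= pref * dx
        Fc[i, 1] -= pref * dy
        Fc[i, 2] -= pref * dz
        Fc[j, 0] += pref * dx
        Fc[j, 1] += pref * dy
        Fc[j, 2] += pref * dz

    # ---- box walls
    L = pp[17]
    Kbox = pp[18]
    sigw = pp[19]
    half = 0.5 * L
    for i in range(n):
        for ax in range(3):
            e, f = _wall(half - pos[i, ax], Kbox, sigw)
            e_total += e
            F[i, ax] -= f
            e, f = _wall(half + pos[i, ax], Kbox, sigw)
            e_total += e
            F[i, ax] += f
    for i in range(M):
        for ax in range(3):
            e, f = _wall(half - cpos[i, ax], Kbox, sigw)
            e_total += e
            Fc[i, ax] -= f
            e, f = _wall(half + cpos[i, ax], Kbox, sigw)
            e_total += e
            Fc[i, ax] += f

    return e_total


@njit(cache=True, fastmath=True)
def compute_forces(
    pos, cpos, F, Fc,
    bond_owner, b0s, ang_owner, th0s, dih_owner, ph0_cs,
    cont_i, cont_j, cont_r0, cont_eps, cont_owner, cont_basin,
    dV, Delta, exv_pairs, n_exv,
    occ, lig_i, lig_j, lig_r0s, lig_eps, lig_site,
    pc_pairs, n_pc, cc_pairs, n_cc,
    pp, w_open, bv, ang_store, dih_store, cont_store, F_mid,
):
    """Complete force evaluation (all classes); returns total energy."""
    Fc_mid = np.zeros_like(Fc)
    e_exv = eval_exv(pos, cpos, exv_pairs, n_exv, pc_pairs, n_pc, pp, F_mid, Fc_mid)
    e = eval_slow(
        pos, cpos, F, Fc, bond_owner, b0s, ang_owner, th0s, dih_owner, ph0_cs,
        cont_i, cont_j, cont_r0, cont_eps, cont_owner, cont_basin, dV, Delta,
        occ, lig_i, lig_j, lig_r0s, lig_eps, lig_site,
        cc_pairs, n_cc, pp, w_open, e_exv,
        bv, ang_store, dih_store, cont_store,
    )
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] += F_mid[i, 0]
        F[i, 1] += F_mid[i, 1]
        F[i, 2] += F_mid[i, 2]
    for i in range(Fc.shape[0]):
        Fc[i, 0] += Fc_mid[i, 0]
        Fc[i, 1] += Fc_mid[i, 1]
        Fc[i, 2] += Fc_mid[i, 2]
    compute_bond_forces(pos, F, b0s, bond_owner, w_open, pp[0])
    return e


# ----------------------------------------------------------- SASA ---------


@njit(cache=True, fastmath=True)
def pocket_sasa_kernel(pos, pocket, sphere, radius):
    """Shrake-Rupley accessible area over pocket beads (kernel version).

    Neighbors are gathered into a contiguous buffer sorted by distance so
    that buried test points are rejected after very few checks.
    """
    npts = sphere.shape[0]
    n = pos.shape[0]
    total = 0.0
    two_r2 = 4.0 * radius * radius
    r2 = radius * radius
    nbr = np.empty((64, 4))
    for pi in range(pocket.shape[0]):
        c = pocket[pi]
        cx = pos[c, 0]
        cy = pos[c, 1]
        cz = pos[c, 2]
        nn = 0
        for k in range(n):
            if k == c:
                continue
            dx = pos[k, 0] - cx
            dy = pos[k, 1] - cy
            dz = pos[k, 2] - cz
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < two_r2 and nn < 64:
                # insertion sort by distance, nearest first
                q = nn
                while q > 0 and nbr[q - 1, 3] > d2:
                    nbr[q, 0] = nbr[q - 1, 0]
                    nbr[q, 1] = nbr[q - 1, 1]
                    nbr[q, 2] = nbr[q - 1, 2]
                    nbr[q, 3] = nbr[q - 1, 3]
                    q -= 1
                nbr[q, 0] = pos[k, 0]
                nbr[q, 1] = pos[k, 1]
                nbr[q, 2] = pos[k, 2]
                nbr[q, 3] = d2
                nn += 1
        exposed = 0
        for p in range(npts):
            sx = cx + radius * sphere[p, 0]
            sy = cy + radius * sphere[p, 1]
            sz = cz + radius * sphere[p, 2]
            buried = False
            for q in range(nn):
                dx = nbr[q, 0] - sx
                dy = nbr[q, 1] - sy
                dz = nbr[q, 2] - sz
                if dx * dx + dy * dy + dz * dz < r2:
                    buried = True
                    break
            if not buried:
                exposed += 1
        total += 4.0 * np.pi * r2 * exposed / npts
    return total


# ------------------------------------------------------- helpers ----------


@njit(cache=True, fastmath=True)
def _com_distances(pos, lid_idx, nmp_idx, core_idx):
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for k in core_idx:
        cx += pos[k, 0]
        cy += pos[k, 1]
        cz += pos[k, 2]
    m = core_idx.shape[0]
    cx /= m
    cy /= m
    cz /= m
    lx = 0.0
    ly = 0.0
    lz = 0.0
    for k in lid_idx:
        lx += pos[k, 0]
        ly += pos[k, 1]
        lz += pos[k, 2]
    m = lid_idx.shape[0]
    lx = lx / m - cx
    ly = ly / m - cy
    lz = lz / m - cz
    nx = 0.0
    ny = 0.0
    nz = 0.0
    for k in nmp_idx:
        nx += pos[k, 0]
        ny += pos[k, 1]
        nz += pos[k, 2]
    m = nmp_idx.shape[0]
    nx = nx / m - cx
    ny = ny / m - cy
    nz = nz / m - cz
    r_lid = math.sqrt(lx * lx + ly * ly + lz * lz)
    r_nmp = math.sqrt(nx * nx + ny * ny + nz * nz)
    return r_lid, r_nmp


@njit(cache=True, fastmath=True)
def _binding_energy_kernel(pos, occ_sp, site, lig_i, lig_j, lig_r0s, lig_eps,
                           lig_site, sigma_lig):
    e = 0.0
    inv2 = 1.0 / (sigma_lig * sigma_lig)
    for k in range(lig_i.shape[0]):
        if lig_site[k] != site:
            continue
        r0 = lig_r0s[k, occ_sp - 1]
        eps = lig_eps[k, occ_sp - 1]
        dx = pos[lig_j[k], 0] - pos[lig_i[k], 0]
        dy = pos[lig_j[k], 1] - pos[lig_i[k], 1]
        dz = pos[lig_j[k], 2] - pos[lig_i[k], 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0
        e += -eps * fexp(-0.5 * dr * dr * inv2)
    return e


@njit(cache=True, fastmath=True)
def _contact_fraction_kernel(pos, sp, site, lig_i, lig_j, lig_r0s, lig_site,
                             sigma_lig):
    formed = 0
    tot = 0
    for k in range(lig_i.shape[0]):
        if lig_site[k] != site:
            continue
        tot += 1
        r0 = lig_r0s[k, sp - 1]
        dx = pos[lig_j[k], 0] - pos[lig_i[k], 0]
        dy = pos[lig_j[k], 1] - pos[lig_i[k], 1]
        dz = pos[lig_j[k], 2] - pos[lig_i[k], 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if abs(r - r0) <= 1.5 * sigma_lig:
            formed += 1
    if tot == 0:
        return 0.0
    return formed / tot


# ------------------------------------------------------- main loop --------


@njit(cache=True, fastmath=True)
def run_segment(
    pos, vel, cpos, cvel, occ,
    bond_owner, b0s, ang_owner, th0s, dih_owner, ph0_cs,
    cont_i, cont_j, cont_r0, cont_eps, cont_owner, cont_basin,
    dV, Delta, excl,
    lig_i, lig_j, lig_r0s, lig_eps, lig_site,
    pocket0, pocket1, sphere, sasa_radius,
    site_S0, site_sigS, site_kon0, site_koff0, site_conc,
    kf, kr, qmin,
    lid_idx, nmp_idx, core_idx,
    pp, n_steps, dt, gamma, kbt, mass_p, mass_c, mc_interval, dt_ms_per_mc,
    respa,
    rng_state,
    trace, trace_stride, events, traj, traj_stride,
    start_step,
):
    """Integrate n_steps of multiple-time-step BAOAB Langevin dynamics with
    the MC ligand-exchange and kMC reaction layers.

    Three force classes: harmonic bonds every step, protein excluded volume
    every ``respa`` steps, and all smooth terms (angles, dihedrals,
    contacts, ligand restraints, crowders, walls — where the double-basin
    mixing weights are refreshed) every ``2 * respa`` steps, applied as
    impulse half-kicks at the class boundaries (r-RESPA within BAOAB;
    ``respa = 1`` makes every class per-step). ``mc_interval`` must be a
    multiple of ``2 * respa``.

    Returns ``(n_events, n_trace, n_frames, final_step)``. ``trace`` rows are
    ``[R_LID-CORE, R_NMP-CORE, occ0, occ1, E_total]`` every ``trace_stride``
    steps; ``events`` rows are ``[step, site, code, species, S, fS, E_bind]``
    with codes 0=bind 1=unbind 2=react_fwd 3=react_rev.
    """
    n = pos.shape[0]
    M = cpos.shape[0]
    F = np.zeros((n, 3))        # fast (bonds)
    Fm = np.zeros((n, 3))       # middle (excluded volume + protein-crowder)
    Fcm = np.zeros((M, 3))      # middle, crowder side of protein-crowder
    Fs = np.zeros((n, 3))       # slow (smooth terms)
    Fc = np.zeros((M, 3))       # slow, crowders
    w_open = np.ones(4)
    bv = np.empty((n - 1, 4))
    ang_store = np.empty((n - 2, 12))
    dih_store = np.empty((n - 3, 14))
    cont_store = np.empty((cont_i.shape[0], 3))
    max_exv = n * 60
    exv_pairs = np.empty((max_exv, 2), dtype=np.int64)
    pc_pairs = np.empty((max(n * max(M, 1) // 4, 16), 2), dtype=np.int64)
    cc_pairs = np.empty((max(M * M // 3, 16), 2), dtype=np.int64)

    mid_every = respa
    slow_every = 2 * respa

    rc_exv = pp[9]
    skin = 1.6
    exv_cut2 = (rc_exv + skin) ** 2
    spc = pp[15]
    scc = pp[14]
    sref = pp[13]
    pc_cut2 = (spc + 1.5 * sref + 2.0) ** 2
    cc_cut2 = (scc + 1.5 * sref + 2.0) ** 2
    nlist_every = 5 * slow_every  # aligned to global steps: continuation-safe

    n_exv = rebuild_exv_list(pos, excl, exv_cut2, exv_pairs)
    n_pc = rebuild_cross_list(pos, cpos, pc_cut2, pc_pairs) if M > 0 else 0
    n_cc = rebuild_self_list(cpos, cc_cut2, cc_pairs) if M > 0 else 0

    # thermostat applied at mid-class boundaries (every ``respa`` steps)
    c1 = math.exp(-gamma * dt * mid_every)
    sig_p = math.sqrt(kbt * (1.0 - c1 * c1) / mass_p)
    sig_c = math.sqrt(kbt * (1.0 - c1 * c1) / mass_c)
    half_dt = 0.5 * dt
    inv_mp = 1.0 / mass_p
    inv_mc = 1.0 / mass_c
    mid_half = 0.5 * mid_every * dt
    slow_half = 0.5 * slow_every * dt

    n_events = 0
    n_trace = 0
    n_frames = 0
    max_events = events.shape[0]
    max_trace = trace.shape[0]
    max_frames = traj.shape[0]

    e_exv = eval_exv(pos, cpos, exv_pairs, n_exv, pc_pairs, n_pc, pp, Fm, Fcm)
    e_total = eval_slow(
        pos, cpos, Fs, Fc, bond_owner, b0s, ang_owner, th0s, dih_owner,
        ph0_cs, cont_i, cont_j, cont_r0, cont_eps, cont_owner, cont_basin,
        dV, Delta, occ, lig_i, lig_j, lig_r0s, lig_eps, lig_site,
        cc_pairs, n_cc, pp, w_open, e_exv,
        bv, ang_store, dih_store, cont_store,
    )
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    compute_bond_forces(pos, F, b0s, bond_owner, w_open, pp[0])

    for step in range(n_steps):
        # class start kicks
        if step % slow_every == 0:
            for i in range(n):
                for ax in range(3):
                    vel[i, ax] += slow_half * Fs[i, ax] * inv_mp
            for i in range(M):
                for ax in range(3):
                    cvel[i, ax] += slow_half * Fc[i, ax] * inv_mc
        if step % mid_every == 0:
            for i in range(n):
                for ax in range(3):
                    vel[i, ax] += mid_half * Fm[i, ax] * inv_mp
            for i in range(M):
                for ax in range(3):
                    cvel[i, ax] += mid_half * Fcm[i, ax] * inv_mc

        # inner velocity-Verlet step with bond forces only
        for i in range(n):
            for ax in range(3):
                v = vel[i, ax] + half_dt * F[i, ax] * inv_mp
                vel[i, ax] = v
                pos[i, ax] += dt * v
        for i in range(M):
            for ax in range(3):
                cpos[i, ax] += dt * cvel[i, ax]
        for i in range(n):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0
        compute_bond_forces(pos, F, b0s, bond_owner, w_open, pp[0])
        for i in range(n):
            for ax in range(3):
                vel[i, ax] += half_dt * F[i, ax] * inv_mp

        gstep = start_step + step + 1

        if (step + 1) % mid_every == 0:
            if gstep % nlist_every == 0:
                n_exv = rebuild_exv_list(pos, excl, exv_cut2, exv_pairs)
                if M > 0:
                    n_pc = rebuild_cross_list(pos, cpos, pc_cut2, pc_pairs)
                    n_cc = rebuild_self_list(cpos, cc_cut2, cc_pairs)
            e_exv = eval_exv(pos, cpos, exv_pairs, n_exv, pc_pairs, n_pc, pp, Fm, Fcm)
            for i in range(n):
                for ax in range(3):
                    vel[i, ax] += mid_half * Fm[i, ax] * inv_mp
                    vel[i, ax] = c1 * vel[i, ax] + sig_p * rng_normal(rng_state)
            for i in range(M):
                for ax in range(3):
                    cvel[i, ax] += mid_half * Fcm[i, ax] * inv_mc
                    cvel[i, ax] = c1 * cvel[i, ax] + sig_c * rng_normal(rng_state)

        if (step + 1) % slow_every == 0:
            # MC layers act at slow boundaries, before the closing kick
            if gstep % mc_interval == 0:
                for site in range(2):
                    if site == 0:
                        S = pocket_sasa_kernel(pos, pocket0, sphere, sasa_radius)
                    else:
                        S = pocket_sasa_kernel(pos, pocket1, sphere, sasa_radius)
                    fS = 1.0 / (1.0 + math.exp(-(S - site_S0[site]) / site_sigS[site]))
                    sp = occ[site]
                    if sp == 0:
                        kon_sub = fS * site_kon0[site] * site_conc[site, 0]
                        kon_prod = fS * site_kon0[site] * site_conc[site, 1]
                        ktot = kon_sub + kon_prod
                        if ktot > 0.0:
                            p = 1.0 - math.exp(-ktot * dt_ms_per_mc)
                            if rng_uniform(rng_state) < p:
                                pick = rng_uniform(rng_state) * ktot
                                new_sp = 1 if pick < kon_sub else 2
                                occ[site] = new_sp
                                if n_events < max_events:
                                    eb = _binding_energy_kernel(
                                        pos, new_sp, site, lig_i, lig_j,
                                        lig_r0s, lig_eps, lig_site, pp[10])
                                    events[n_events, 0] = gstep
                                    events[n_events, 1] = site
                                    events[n_events, 2] = 0.0
                                    events[n_events, 3] = new_sp
                                    events[n_events, 4] = S
                                    events[n_events, 5] = fS
                                    events[n_events, 6] = eb
                                    n_events += 1
                    else:
                        eb = _binding_energy_kernel(
                            pos, sp, site, lig_i, lig_j, lig_r0s, lig_eps,
                            lig_site, pp[10])
                        koff = fS * site_koff0[site, sp - 1] * math.exp(eb / kbt)
                        p = 1.0 - math.exp(-koff * dt_ms_per_mc)
                        if rng_uniform(rng_state) < p:
                            occ[site] = 0
                            if n_events < max_events:
                                events[n_events, 0] = gstep
                                events[n_events, 1] = site
                                events[n_events, 2] = 1.0
                                events[n_events, 3] = sp
                                events[n_events, 4] = S
                                events[n_events, 5] = fS
                                events[n_events, 6] = eb
                                n_events += 1

                r_lid, r_nmp = _com_distances(pos, lid_idx, nmp_idx, core_idx)
                closed = (r_lid < pp[20]) and (r_nmp < pp[21])
                if closed:
                    direction = 0
                    if occ[0] == 1 and occ[1] == 1 and kf > 0.0:
                        direction = 1
                    elif occ[0] == 2 and occ[1] == 2 and kr > 0.0:
                        direction = 2
                    if direction > 0:
                        sp = direction
                        q0 = _contact_fraction_kernel(pos, sp, 0, lig_i, lig_j,
                                                      lig_r0s, lig_site, pp[10])
                        q1 = _contact_fraction_kernel(pos, sp, 1, lig_i, lig_j,
                                                      lig_r0s, lig_site, pp[10])
                        if q0 >= qmin and q1 >= qmin:
                            rate = kf if direction == 1 else kr
                            if rng_uniform(rng_state) < 1.0 - math.exp(-rate * dt_ms_per_mc):
                                newsp = 2 if direction == 1 else 1
                                occ[0] = newsp
                                occ[1] = newsp
                                if n_events < max_events:
                                    events[n_events, 0] = gstep
                                    events[n_events, 1] = -1.0
                                    events[n_events, 2] = 2.0 if direction == 1 else 3.0
                                    events[n_events, 3] = 0.0
                                    events[n_events, 4] = 0.0
                                    events[n_events, 5] = 0.0
                                    events[n_events, 6] = 0.0
                                    n_events += 1

            e_total = eval_slow(
                pos, cpos, Fs, Fc, bond_owner, b0s, ang_owner, th0s,
                dih_owner, ph0_cs, cont_i, cont_j, cont_r0, cont_eps,
                cont_owner, cont_basin, dV, Delta, occ, lig_i, lig_j,
                lig_r0s, lig_eps, lig_site, cc_pairs, n_cc,
                pp, w_open, e_exv, bv, ang_store, dih_store, cont_store,
            )
            for i in range(n):
                for ax in range(3):
                    vel[i, ax] += slow_half * Fs[i, ax] * inv_mp
            for i in range(M):
                for ax in range(3):
                    cvel[i, ax] += slow_half * Fc[i, ax] * inv_mc

        if (step + 1) % trace_stride == 0 and n_trace < max_trace:
            r_lid, r_nmp = _com_distances(pos, lid_idx, nmp_idx, core_idx)
            trace[n_trace, 0] = r_lid
            trace[n_trace, 1] = r_nmp
            trace[n_trace, 2] = occ[0]
            trace[n_trace, 3] = occ[1]
            trace[n_trace, 4] = e_total
            n_trace += 1

        if traj_stride > 0 and (step + 1) % traj_stride == 0 and n_frames < max_frames:
            for i in range(n):
                for ax in range(3):
                    traj[n_frames, i, ax] = pos[i, ax]
            for i in range(M):
                for ax in range(3):
                    traj[n_frames, n + i, ax] = cpos[i, ax]
            n_frames += 1

    return n_events, n_trace, n_frames, start_step + n_steps
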