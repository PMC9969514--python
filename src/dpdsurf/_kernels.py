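"""Numba kernels for DPD force evaluation.

Everything here operates on flat arrays in reduced units.  The pairwise
random force uses a counter-based (hash) stream keyed on (seed, step, i, j),
so a trajectory is bit-reproducible regardless of pair iteration order and
the same pair draws the same number on both beads (momentum conservation is
exact by construction).
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_C1 = U64(0x9E3779B97F4A7C15)
_C2 = U64(0xBF58476D1CE4E5B9)
_C3 = U64(0x94D049BB133111EB)
_P1 = U64(0xD6E8FEB86659FD93)
_INV_2_64 = 1.0 / 18446744073709551616.0
_SQRT3 = 1.7320508075688772


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z + _C1) * _P1
    z ^= z >> U64(30)
    z *= _C2
    z ^= z >> U64(27)
    z *= _C3
    z ^= z >> U64(31)
    return z


@njit(cache=True, inline="always")
def _pair_zeta(seed, step, i, j):
    """Uniform random with zero mean, unit variance, for pair (i<j) at step."""
    h = _mix64(U64(seed) ^ (U64(step) * _C2))
    h = _mix64(h ^ (U64(i) * _C3) ^ U64(j))
    u = np.float64(h) * _INV_2_64
    return _SQRT3 * (2.0 * u - 1.0)


@njit(cache=True)
def build_pair_list(pos, box, cutoff, pi, pj, ex, ey, ez, pr):
    """All pairs within ``cutoff`` under the minimum image convention.

    Uses a linked-cell search when at least 3 cells fit along every axis,
    otherwise falls back to an O(n^2) double loop (tiny systems).  Returns
    the number of pairs, or -1 if the scratch arrays are too small.
    """
    n = pos.shape[0]
    cap = pi.shape[0]
    ncx = int(box[0] / cutoff)
    ncy = int(box[1] / cutoff)
    ncz = int(box[2] / cutoff)
    count = 0
    if ncx < 3 or ncy < 3 or ncz < 3:
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= box[0] * np.rint(dx / box[0])
                dy -= box[1] * np.rint(dy / box[1])
                dz -= box[2] * np.rint(dz / box[2])
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < cutoff * cutoff and r2 > 0.0:
                    if count >= cap:
                        return -1
                    r = np.sqrt(r2)
                    pi[count] = i
                    pj[count] = j
                    ex[count] = dx / r
                    ey[count] = dy / r
                    ez[count] = dz / r
                    pr[count] = r
                    count += 1
        return count
    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / box[0] * ncx) % ncx
        cy = int(pos[i, 1] / box[1] * ncy) % ncy
        cz = int(pos[i, 2] / box[2] * ncz) % ncz
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i
    # half stencil: self + 13 neighbours
    offs = np.array(
        [
            [0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
            [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1],
            [0, 1, 1], [0, 1, -1], [1, 1, 1], [1, 1, -1],
            [1, -1, 1], [1, -1, -1],
        ],
        dtype=np.int64,
    )
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                for o in range(offs.shape[0]):
                    c2x = (cx + offs[o, 0]) % ncx
                    c2y = (cy + offs[o, 1]) % ncy
                    c2z = (cz + offs[o, 2]) % ncz
                    c2 = (c2x * ncy + c2y) * ncz + c2z
                    i = head[c]
                    while i >= 0:
                        if c2 == c:
                            j = nxt[i]
                        else:
                            j = head[c2]
                        while j >= 0:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= box[0] * np.rint(dx / box[0])
                            dy -= box[1] * np.rint(dy / box[1])
                            dz -= box[2] * np.rint(dz / box[2])
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 < cutoff * cutoff and r2 > 0.0:
                                if count >= cap:
                                    return -1
                                r = np.sqrt(r2)
                                pi[count] = i
                                pj[count] = j
                                ex[count] = dx / r
                                ey[count] = dy / r
                                ez[count] = dz / r
                                pr[count] = r
                                count += 1
                            j = nxt[j]
                        i = nxt[i]
    return count


@njit(cache=True)
def conservative_random_forces(
    npairs, pi, pj, ex, ey, ez, pr, types, A, R, sigma, rdiss, inv_sqrt_dt,
    seed, step, do_random, f,
):
    """Soft repulsions plus the pairwise random force.

    Adds forces into ``f`` (caller zeroes it).  Returns (virial, pe) where
    the virial sum r_ij . F_ij covers the conservative part only.
    """
    virial = 0.0
    pe = 0.0
    for p in range(npairs):
        i = pi[p]
        j = pj[p]
        r = pr[p]
        ti = types[i]
        tj = types[j]
        Rij = R[ti, tj]
        fmag = 0.0
        if r < Rij:
            Aij = A[ti, tj]
            q = 1.0 - r / Rij
            fc = Aij * q
            pe += 0.5 * Aij * Rij * q * q
            virial += fc * r
            fmag += fc
        if do_random and r < rdiss:
            wr = 1.0 - r / rdiss
            zeta = _pair_zeta(seed, step, i, j)
            fmag += sigma * wr * zeta * inv_sqrt_dt
        if fmag != 0.0:
            f[i, 0] += fmag * ex[p]
            f[i, 1] += fmag * ey[p]
            f[i, 2] += fmag * ez[p]
            f[j, 0] -= fmag * ex[p]
            f[j, 1] -= fmag * ey[p]
            f[j, 2] -= fmag * ez[p]
    return virial, pe


@njit(cache=True)
def dissipative_forces(npairs, pi, pj, ex, ey, ez, pr, vel, gamma, rdiss, f):
    """Pairwise dissipative force -gamma w_D(r) (e.v_ij) e, w_D = (1-r/rd)^2."""
    for p in range(npairs):
        r = pr[p]
        if r < rdiss:
            i = pi[p]
            j = pj[p]
            wr = 1.0 - r / rdiss
            vdote = (
                (vel[i, 0] - vel[j, 0]) * ex[p]
                + (vel[i, 1] - vel[j, 1]) * ey[p]
                + (vel[i, 2] - vel[j, 2]) * ez[p]
            )
            fmag = -gamma * wr * wr * vdote
            f[i, 0] += fmag * ex[p]
            f[i, 1] += fmag * ey[p]
            f[i, 2] += fmag * ez[p]
            f[j, 0] -= fmag * ex[p]
            f[j, 1] -= fmag * ey[p]
            f[j, 2] -= fmag * ez[p]


@njit(cache=True)
def bond_forces(pos, box, bonds, bond_r0, k_b, f):
    """Harmonic bonds U = k_b (r - r0)^2 (as-printed convention, no 1/2)."""
    virial = 0.0
    pe = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        dr = r - bond_r0[b]
        pe += k_b * dr * dr
        fmag = -2.0 * k_b * dr  # along e_ij on bead i
        virial += fmag * r
        fx = fmag * dx / r
        fy = fmag * dy / r
        fz = fmag * dz / r
        f[i, 0] += fx
        f[i, 1] += fy
        f[i, 2] += fz
        f[j, 0] -= fx
        f[j, 1] -= fy
        f[j, 2] -= fz
    return virial, pe


@njit(cache=True)
def angle_forces(pos, box, angles, angle_ka, angle_t0, f):
    """Harmonic angles U = 1/2 k_a (theta - theta0)^2, theta in radians.

    Collinear geometries are guarded: as sin(theta) -> 0 the transverse
    direction is ill-defined and the force smoothly approaches zero for
    theta0 = pi; for bent equilibria a small floor on sin(theta) keeps the
    force finite.
    """
    virial = 0.0
    pe = 0.0
    for t in range(angles.shape[0]):
        i = angles[t, 0]
        j = angles[t, 1]
        k = angles[t, 2]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        by = pos[k, 1] - pos[j, 1]
        bz = pos[k, 2] - pos[j, 2]
        ax -= box[0] * np.rint(ax / box[0])
        ay -= box[1] * np.rint(ay / box[1])
        az -= box[2] * np.rint(az / box[2])
        bx -= box[0] * np.rint(bx / box[0])
        by -= box[1] * np.rint(by / box[1])
        bz -= box[2] * np.rint(bz / box[2])
        la = np.sqrt(ax * ax + ay * ay + az * az)
        lb = np.sqrt(bx * bx + by * by + bz * bz)
        if la < 1e-12 or lb < 1e-12:
            continue
        c = (ax * bx + ay * by + az * bz) / (la * lb)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dth = theta - angle_t0[t]
        ka = angle_ka[t]
        pe += 0.5 * ka * dth * dth
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        coef = ka * dth / s
        # F_i = coef/la * (b_hat - c a_hat); F_k = coef/lb * (a_hat - c b_hat)
        fix = coef / la * (bx / lb - c * ax / la)
        fiy = coef / la * (by / lb - c * ay / la)
        fiz = coef / la * (bz / lb - c * az / la)
        fkx = coef / lb * (ax / la - c * bx / lb)
        fky = coef / lb * (ay / la - c * by / lb)
        fkz = coef / lb * (az / la - c * bz / lb)
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz
        virial += fix * ax + fiy * ay + fiz * az + fkx * bx + fky * by + fkz * bz
    return virial, pe


@njit(cache=True)
def shardlow_pass(
    npairs, pi, pj, ex, ey, ez, pr, vel, gamma, sigma, rdiss, dt, seed, step
):
    """Pairwise dissipative+random update (Shardlow splitting, S1).

    For each pair the relative velocity along the bead axis undergoes an
    explicit half-step followed by an implicit half-step of the
    Ornstein-Uhlenbeck process, sharing one random number; this leaves the
    per-pair stationary kinetic variance exact for any time step.  Pairs
    are processed sequentially in pair-list order.
    """
    for p in range(npairs):
        r = pr[p]
        if r >= rdiss:
            continue
        i = pi[p]
        j = pj[p]
        w = 1.0 - r / rdiss
        lam = gamma * w * w * dt
        B = sigma * w * np.sqrt(dt) * _pair_zeta(seed, step, i, j)
        u = (
            (vel[i, 0] - vel[j, 0]) * ex[p]
            + (vel[i, 1] - vel[j, 1]) * ey[p]
            + (vel[i, 2] - vel[j, 2]) * ez[p]
        )
        phi = 0.5 * (B - lam * u)
        vel[i, 0] += phi * ex[p]
        vel[i, 1] += phi * ey[p]
        vel[i, 2] += phi * ez[p]
        vel[j, 0] -= phi * ex[p]
        vel[j, 1] -= phi * ey[p]
        vel[j, 2] -= phi * ez[p]
        u1 = u + 2.0 * phi
        phi2 = (B - lam * u1) / (2.0 * (1.0 + lam))
        vel[i, 0] += phi2 * ex[p]
        vel[i, 1] += phi2 * ey[p]
        vel[i, 2] += phi2 * ez[p]
        vel[j, 0] -= phi2 * ex[p]
        vel[j, 1] -= phi2 * ey[p]
        vel[j, 2] -= phi2 * ez[p]
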