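"""Numba kernels for the DPD pair forces and bonded terms.

The random (thermostat) force uses a counter-based Gaussian stream: each
unordered pair (i, j) at a given step hashes to its own normal deviate.  This
makes the force field independent of pair-iteration order — the cell-list
kernel and a plain all-pairs loop produce identical forces to round-off — and
trajectories bitwise reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
import numba as nb

U64 = np.uint64
_SM_GAMMA = U64(0x9E3779B97F4A7C15)
_SM_M1 = U64(0xBF58476D1CE4E5B9)
_SM_M2 = U64(0x94D049BB133111EB)
_P1 = U64(0x8593AF1F7BEF9E6D)
_P2 = U64(0xD6E8FEB86659FD93)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53

# neighbour-cell offsets covering each unordered cell pair once
_OFFSETS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 1, 0],
        [1, 0, 1],
        [0, 1, 1],
        [1, 1, 1],
        [1, -1, 0],
        [1, 0, -1],
        [0, 1, -1],
        [1, -1, 1],
        [1, 1, -1],
        [-1, 1, 1],
    ],
    dtype=np.int64,
)


@nb.njit(inline="always", cache=True)
def _splitmix(x):
    x = x + _SM_GAMMA
    z = x
    z = (z ^ (z >> U64(30))) * _SM_M1
    z = (z ^ (z >> U64(27))) * _SM_M2
    return z ^ (z >> U64(31))


@nb.njit(inline="always", cache=True)
def pair_gauss(i, j, salt):
    """Standard-normal deviate keyed by the unordered pair and a step salt."""
    if i < j:
        lo, hi = U64(i), U64(j)
    else:
        lo, hi = U64(j), U64(i)
    h1 = _splitmix(U64(salt) ^ (lo * _P1) ^ (hi * _P2))
    h2 = _splitmix(h1)
    u1 = (float(h1 >> U64(11)) + 1.0) * _INV53  # (0, 1]
    u2 = float(h2 >> U64(11)) * _INV53
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(2.0 * np.pi * u2)


@nb.njit(cache=True)
def build_cells(pos, box, ncell):
    n = pos.shape[0]
    head = -np.ones(ncell * ncell * ncell, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    lc = box / ncell
    for i in range(n):
        ci = min(int(pos[i, 0] / lc), ncell - 1)
        cj = min(int(pos[i, 1] / lc), ncell - 1)
        ck = min(int(pos[i, 2] / lc), ncell - 1)
        c = (ci * ncell + cj) * ncell + ck
        nxt[i] = head[c]
        head[c] = i
    return head, nxt


@nb.njit(inline="always", cache=True)
def _pair_accum(
    i, j, pos, vel, types, amp, rng, box, gamma, sigma, inv_sqrt_dt, salt, thermo, F, acc
):
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    dx -= box * np.round(dx / box)
    dy -= box * np.round(dy / box)
    dz -= box * np.round(dz / box)
    r2 = dx * dx + dy * dy + dz * dz
    ti = types[i]
    tj = types[j]
    rc = rng[ti, tj]
    rmax = rc if rc > 1.0 else 1.0
    if r2 >= rmax * rmax:
        return
    if r2 < 1e-24:
        acc[1] += 1.0  # coincident beads: finite potential, undefined direction
        return
    r = np.sqrt(r2)
    ex = dx / r
    ey = dy / r
    ez = dz / r
    ft = 0.0
    if r < rc:
        fc = amp[ti, tj] * (1.0 - r / rc)
        ft += fc
        acc[0] += fc * r  # conservative virial
    if thermo and r < 1.0:
        w = 1.0 - r
        dvx = vel[i, 0] - vel[j, 0]
        dvy = vel[i, 1] - vel[j, 1]
        dvz = vel[i, 2] - vel[j, 2]
        rv = ex * dvx + ey * dvy + ez * dvz
        ft += -gamma * w * w * rv
        ft += sigma * w * pair_gauss(i, j, salt) * inv_sqrt_dt
    F[i, 0] += ft * ex
    F[i, 1] += ft * ey
    F[i, 2] += ft * ez
    F[j, 0] -= ft * ex
    F[j, 1] -= ft * ey
    F[j, 2] -= ft * ez


@nb.njit(cache=True)
def nonbonded_cells(
    pos, vel, types, amp, rng, box, ncell, head, nxt, gamma, sigma, inv_sqrt_dt, salt, thermo
):
    """Cell-list pair loop. Returns (forces, conservative virial, n_coincident)."""
    n = pos.shape[0]
    F = np.zeros((n, 3))
    acc = np.zeros(2)
    for ci in range(ncell):
        for cj in range(ncell):
            for ck in range(ncell):
                c0 = (ci * ncell + cj) * ncell + ck
                for off in range(14):
                    ni = (ci + _OFFSETS[off, 0]) % ncell
                    nj = (cj + _OFFSETS[off, 1]) % ncell
                    nk = (ck + _OFFSETS[off, 2]) % ncell
                    c1 = (ni * ncell + nj) * ncell + nk
                    i = head[c0]
                    while i >= 0:
                        j = nxt[i] if c1 == c0 else head[c1]
                        while j >= 0:
                            _pair_accum(
                                i, j, pos, vel, types, amp, rng, box,
                                gamma, sigma, inv_sqrt_dt, salt, thermo, F, acc,
                            )
                            j = nxt[j]
                        i = nxt[i]
    return F, acc[0], int(acc[1])


@nb.njit(cache=True)
def nonbonded_allpairs(
    pos, vel, types, amp, rng, box, gamma, sigma, inv_sqrt_dt, salt, thermo
):
    """O(N^2) pair loop used when the box holds fewer than 3 cells per side."""
    n = pos.shape[0]
    F = np.zeros((n, 3))
    acc = np.zeros(2)
    for i in range(n):
        for j in range(i + 1, n):
            _pair_accum(
                i, j, pos, vel, types, amp, rng, box,
                gamma, sigma, inv_sqrt_dt, salt, thermo, F, acc,
            )
    return F, acc[0], int(acc[1])


@nb.njit(cache=True)
def bonded_kernel(
    pos, box, kb, bond_i, bond_j, bond_r0, ka, ang_i, ang_j, ang_k, ang_t0
):
    """Harmonic bond and angle forces (exact gradients). Returns (F, virial, U)."""
    n = pos.shape[0]
    F = np.zeros((n, 3))
    virial = 0.0
    energy = 0.0
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * np.round(dx / box)
        dy -= box * np.round(dy / box)
        dz -= box * np.round(dz / box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        f = -kb * (r - bond_r0[b])  # force on i along +r_ij
        energy += 0.5 * kb * (r - bond_r0[b]) ** 2
        fx = f * dx / r
        fy = f * dy / r
        fz = f * dz / r
        F[i, 0] += fx
        F[i, 1] += fy
        F[i, 2] += fz
        F[j, 0] -= fx
        F[j, 1] -= fy
        F[j, 2] -= fz
        virial += f * r
    for a in range(ang_i.shape[0]):
        i = ang_i[a]
        j = ang_j[a]
        k = ang_k[a]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        ux -= box * np.round(ux / box)
        uy -= box * np.round(uy / box)
        uz -= box * np.round(uz / box)
        vx -= box * np.round(vx / box)
        vy -= box * np.round(vy / box)
        vz -= box * np.round(vz / box)
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if ru < 1e-12 or rv < 1e-12:
            continue
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8  # stable small-sine branch near collinearity
        energy += 0.5 * ka * (theta - ang_t0[a]) ** 2
        coeff = ka * (theta - ang_t0[a]) / s  # -dE/dtheta * dtheta/dcos
        # dcos/dr_i and dcos/dr_k
        gix = (vx / (ru * rv)) - c * ux / (ru * ru)
        giy = (vy / (ru * rv)) - c * uy / (ru * ru)
        giz = (vz / (ru * rv)) - c * uz / (ru * ru)
        gkx = (ux / (ru * rv)) - c * vx / (rv * rv)
        gky = (uy / (ru * rv)) - c * vy / (rv * rv)
        gkz = (uz / (ru * rv)) - c * vz / (rv * rv)
        fix = coeff * gix
        fiy = coeff * giy
        fiz = coeff * giz
        fkx = coeff * gkx
        fky = coeff * gky
        fkz = coeff * gkz
        F[i, 0] += fix
        F[i, 1] += fiy
        F[i, 2] += fiz
        F[k, 0] += fkx
        F[k, 1] += fky
        F[k, 2] += fkz
        F[j, 0] -= fix + fkx
        F[j, 1] -= fiy + fky
        F[j, 2] -= fiz + fkz
        virial += ux * fix + uy * fiy + uz * fiz
        virial += vx * fkx + vy * fky + vz * fkz
    return F, virial, energy


def step_salt(seed: int, step: int) -> int:
    """Per-step salt for the counter-based thermostat noise (int64-safe)."""
    return (seed * 0x8593AF1F7BEF9E6D + step * 0xD6E8FEB86659FD93) & (2**63 - 1)
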