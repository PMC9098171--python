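"""Independent reference implementations (oracles) used by the tests.

Everything here is deliberately naive: O(N^2) pair loops, direct lattice
sums, finite differences.  The only piece shared with the package is the
counter-based per-pair noise stream (setsolv._kernels.pair_gauss), since the
random force is defined *by* that stream; the force expressions and pair
enumeration around it are reimplemented from scratch.
"""

from __future__ import annotations

import numpy as np

from setsolv._kernels import pair_gauss


def min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def brute_nonbonded(
    pos: np.ndarray,
    vel: np.ndarray,
    types: np.ndarray,
    amp: np.ndarray,
    rng_m: np.ndarray,
    box: float,
    gamma: float = 0.0,
    sigma: float = 0.0,
    inv_sqrt_dt: float = 1.0,
    salt: int = 0,
    thermo: bool = False,
):
    """All-pairs DPD nonbonded forces: conservative + dissipative + random."""
    n = len(pos)
    F = np.zeros((n, 3))
    vir = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = min_image(pos[i] - pos[j], box)
            r = float(np.linalg.norm(d))
            if r < 1e-12:
                continue
            e = d / r
            ft = 0.0
            rc = rng_m[types[i], types[j]]
            if r < rc:
                fc = amp[types[i], types[j]] * (1.0 - r / rc)
                ft += fc
                vir += fc * r
            if thermo and r < 1.0:
                w = 1.0 - r
                rv = float(e @ (vel[i] - vel[j]))
                ft += -gamma * w * w * rv
                ft += sigma * w * pair_gauss(i, j, salt) * inv_sqrt_dt
            F[i] += ft * e
            F[j] -= ft * e
    return F, vir


def brute_bonded_energy(
    pos: np.ndarray,
    box: float,
    kb: float,
    bonds: list[tuple[int, int, float]],
    ka: float,
    angles: list[tuple[int, int, int, float]],
) -> float:
    """Direct evaluation of the harmonic bond + angle energy."""
    u = 0.0
    for i, j, r0 in bonds:
        r = float(np.linalg.norm(min_image(pos[i] - pos[j], box)))
        u += 0.5 * kb * (r - r0) ** 2
    for i, j, k, t0 in angles:
        a = min_image(pos[i] - pos[j], box)
        b = min_image(pos[k] - pos[j], box)
        c = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        theta = float(np.arccos(np.clip(c, -1.0, 1.0)))
        u += 0.5 * ka * (theta - t0) ** 2
    return u


def brute_cluster(
    positions: np.ndarray,
    box: float,
    mol_of_bead: np.ndarray,
    is_tail: np.ndarray,
    molecules: np.ndarray,
    cutoff: float,
) -> list[frozenset[int]]:
    """All-pairs single-linkage clustering of molecules by tail contact."""
    adj: dict[int, set[int]] = {int(m): set() for m in molecules}
    tails = np.flatnonzero(is_tail)
    for a_i in range(len(tails)):
        for b_i in range(a_i + 1, len(tails)):
            bi, bj = tails[a_i], tails[b_i]
            mi, mj = int(mol_of_bead[bi]), int(mol_of_bead[bj])
            if mi == mj:
                continue
            d = min_image(positions[bi] - positions[bj], box)
            if float(d @ d) < cutoff**2:
                adj[mi].add(mj)
                adj[mj].add(mi)
    seen: set[int] = set()
    parts: list[frozenset[int]] = []
    for m in molecules:
        m = int(m)
        if m in seen:
            continue
        comp = {m}
        stack = [m]
        seen.add(m)
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    comp.add(y)
                    stack.append(y)
        parts.append(frozenset(comp))
    return parts


def slater_image_sum(
    positions: np.ndarray,
    charges: np.ndarray,
    box: float,
    gamma: float,
    beta: float,
    n_images: int = 16,
) -> float:
    """Direct periodic-image sum of the smeared-charge pair energy.

    Includes the interaction of every charge with all periodic images of
    every charge (itself included, n != 0).  Spherically truncated at
    ``n_images`` shells; converges for neutral, cubically symmetric toys.
    """
    c = gamma / (4.0 * np.pi)
    rng = np.arange(-n_images, n_images + 1)
    shifts = (
        np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
        * box
    )
    n = len(charges)
    total = 0.0
    for i in range(n):
        for j in range(n):
            d = positions[i] - positions[j] + shifts  # (M, 3)
            r = np.linalg.norm(d, axis=1)
            if i == j:
                r = r[r > 1e-9]  # drop the n = 0 self term
            u = c * charges[i] * charges[j] / r * (
                1.0 - (1.0 + beta * r) * np.exp(-2.0 * beta * r)
            )
            total += 0.5 * float(u.sum())
    return total
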