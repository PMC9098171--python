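"""Slater-smeared electrostatics with Ewald summation.

Soft DPD beads would collapse onto point charges, so each charge is smeared
with a Slater-type exponential density.  The resulting pair potential (in kBT,
lengths in rc) is

    u(r) = (Gamma qi qj / 4 pi r) * [1 - (1 + beta* r) exp(-2 beta* r)]

which is finite at contact, u(0) = Gamma qi qj beta* / 4 pi, and has the bare
Coulomb tail.  Periodicity is handled by a standard point-charge Ewald sum
plus the short-ranged correction (u_slater - u_coulomb), which decays as
exp(-2 beta* r) and is truncated at the real-space cutoff.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import erfc

__all__ = [
    "ElectrostaticSettings",
    "slater_pair_energy",
    "slater_pair_force",
    "ewald_total",
]


@dataclass(frozen=True)
class ElectrostaticSettings:
    """Coupling and Ewald discretization parameters.

    ``kcut`` follows the wave-vector magnitude convention: all k = 2 pi n / L
    with |k| <= kcut (rc^-1) enter the reciprocal sum.
    """

    gamma: float = 15.94  # dimensionless coupling e^2/(kB T eps0 eps_r rc)
    beta_star: float = 0.929  # Slater smearing parameter, rc^-1
    rcut_real: float = 3.0  # real-space cutoff, rc
    kcut: float = 5.0  # reciprocal-space cutoff, rc^-1
    alpha: float = 1.0  # Ewald splitting width, rc^-1

    def __post_init__(self) -> None:
        if min(self.gamma, self.beta_star, self.rcut_real, self.kcut, self.alpha) <= 0:
            raise ValueError("all electrostatic settings must be positive")

    @property
    def coulomb_prefactor(self) -> float:
        """C such that the bare pair energy is C qi qj / r."""
        return self.gamma / (4.0 * math.pi)


_R_TINY = 1e-6


def slater_pair_energy(
    r: float | np.ndarray,
    qi: float,
    qj: float,
    settings: ElectrostaticSettings = ElectrostaticSettings(),
) -> float | np.ndarray:
    """Smeared-charge pair energy in kBT; total function of r >= 0."""
    if qi * qj == 0:
        return np.zeros_like(np.asarray(r, dtype=float)) if np.ndim(r) else 0.0
    c = settings.coulomb_prefactor * qi * qj
    b = settings.beta_star
    r_arr = np.asarray(r, dtype=float)
    small = r_arr < _R_TINY
    safe = np.where(small, 1.0, r_arr)
    u = c / safe * (1.0 - (1.0 + b * safe) * np.exp(-2.0 * b * safe))
    u = np.where(small, c * b, u)
    return float(u) if np.ndim(r) == 0 else u


def slater_pair_force(
    r: float | np.ndarray,
    qi: float,
    qj: float,
    settings: ElectrostaticSettings = ElectrostaticSettings(),
) -> float | np.ndarray:
    """Magnitude -du/dr of the smeared pair interaction (positive = repulsive
    along +r for like charges)."""
    if qi * qj == 0:
        return np.zeros_like(np.asarray(r, dtype=float)) if np.ndim(r) else 0.0
    c = settings.coulomb_prefactor * qi * qj
    b = settings.beta_star
    r_arr = np.asarray(r, dtype=float)
    small = r_arr < _R_TINY
    safe = np.where(small, 1.0, r_arr)
    e = np.exp(-2.0 * b * safe)
    g = 1.0 - (1.0 + b * safe) * e
    gp = b * e * (1.0 + 2.0 * b * safe)
    f = c * (g / safe**2 - gp / safe)  # -du/dr
    f = np.where(small, 0.0, f)  # force vanishes at contact by symmetry
    return float(f) if np.ndim(r) == 0 else f


def _kvectors(box: float, kcut: float) -> np.ndarray:
    nmax = int(kcut * box / (2.0 * math.pi))
    ks = []
    for n in itertools.product(range(-nmax, nmax + 1), repeat=3):
        if n == (0, 0, 0):
            continue
        k = 2.0 * math.pi * np.array(n) / box
        if np.dot(k, k) <= kcut * kcut:
            ks.append(k)
    return np.array(ks)


def ewald_total(
    positions: np.ndarray,
    charges: np.ndarray,
    box: float,
    settings: ElectrostaticSettings = ElectrostaticSettings(),
) -> tuple[float, np.ndarray]:
    """Total electrostatic energy (kBT) and per-bead forces.

    Point-charge Ewald (real + reciprocal + self) plus the truncated
    real-space smearing correction.  Requires a neutral system and a box at
    least twice the real-space cutoff.
    """
    charges = np.asarray(charges, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = len(charges)
    forces = np.zeros((n, 3))
    if not np.any(charges):
        return 0.0, forces
    if abs(charges.sum()) > 1e-9:
        raise ValueError("Ewald sum requires a charge-neutral system")
    if box < 2.0 * settings.rcut_real:
        raise ValueError("box side must be at least twice the real-space cutoff")
    c = settings.coulomb_prefactor
    a = settings.alpha
    b = settings.beta_star

    # real space: erfc screening plus the smearing correction, both truncated
    tree = cKDTree(np.mod(positions, box), boxsize=box)
    pairs = tree.query_pairs(settings.rcut_real, output_type="ndarray")
    energy = 0.0
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = positions[i] - positions[j]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
        qq = charges[i] * charges[j]
        e2br = np.exp(-2.0 * b * r)
        # u = C qq [ (1-(1+br)e^-2br)/r - erf(ar)/r ]   (finite at r -> 0)
        g = 1.0 - (1.0 + b * r) * e2br
        u = c * qq * (g / r - (1.0 - erfc(a * r)) / r)
        energy += float(u.sum())
        gp = b * e2br * (1.0 + 2.0 * b * r)
        derf = 2.0 * a / math.sqrt(math.pi) * np.exp(-(a * r) ** 2)
        # f = -du/dr
        f = c * qq * ((g / r**2 - gp / r) - ((1.0 - erfc(a * r)) / r**2 - derf / r))
        fvec = (f / r)[:, None] * d
        np.add.at(forces, i, fvec)
        np.add.at(forces, j, -fvec)

    # reciprocal space
    kvecs = _kvectors(box, settings.kcut)
    if len(kvecs):
        k2 = (kvecs**2).sum(axis=1)
        phase = positions @ kvecs.T  # (n, K)
        cosp = np.cos(phase)
        sinp = np.sin(phase)
        re = charges @ cosp
        im = charges @ sinp
        vol = box**3
        coeff = c * 4.0 * math.pi / vol * np.exp(-k2 / (4.0 * a * a)) / k2
        energy += float(0.5 * (coeff * (re**2 + im**2)).sum())
        # F_i = qi * sum_k coeff * k * (sin(k.ri) Re - cos(k.ri) Im)
        w = coeff[None, :] * (sinp * re[None, :] - cosp * im[None, :])
        forces += charges[:, None] * (w @ kvecs)

    # self energy of the Gaussian screening charges
    energy -= c * a / math.sqrt(math.pi) * float((charges**2).sum())
    return energy, forces
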