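"""DPD simulation engine.

Velocity-Verlet integration of soft conservative repulsions, harmonic bonded
terms, the pairwise dissipative+random thermostat (fluctuation-dissipation:
``sigma^2 = 2 gamma kBT``) and, for charged systems, Slater-smeared Ewald
electrostatics.  Beads have unit mass; kBT = 1; lengths are in rc.  The
thermostat weight function is ``w(r) = 1 - r`` on the unit range regardless of
the per-pair conservative cutoff.

Observables: kinetic temperature ``T = 2 KE / (3N - 3)`` and virial pressure
``P = (N T + W/3) / V`` where ``W`` accumulates conservative and bonded pair
virials (thermostat forces excluded).  Constant pressure uses Berendsen-style
isotropic box rescaling toward the target.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .electrostatics import ElectrostaticSettings, ewald_total
from .forcefield import (
    BondedTerms,
    ForceField,
    MissingParameterError,
    MoleculeTopology,
    WATER,
)

__all__ = [
    "SimState",
    "SimSettings",
    "Composition",
    "System",
    "Trajectory",
    "TrajectoryFrame",
    "ObservableSummary",
    "EngineError",
    "InstabilityError",
    "build_system",
    "initial_state",
    "conservative_forces",
    "bonded_forces",
    "integrate_step",
    "run_simulation",
    "measure_observables",
]

#: Known DPD water reference pressure in reduced units (a=25, rho=3).
WATER_PRESSURE = 23.7


class EngineError(RuntimeError):
    pass


class InstabilityError(EngineError):
    """A bead moved more than the per-step displacement guard."""


@dataclass
class SimState:
    """Instantaneous particle state in a periodic cubic box (side in rc)."""

    positions: np.ndarray  # (N, 3), wrapped into [0, L)
    velocities: np.ndarray  # (N, 3)
    type_ids: np.ndarray  # (N,) indices into type_names
    type_names: tuple[str, ...]
    box: float
    step: int = 0

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def bead_names(self) -> list[str]:
        return [self.type_names[t] for t in self.type_ids]

    def copy(self) -> "SimState":
        return SimState(
            self.positions.copy(),
            self.velocities.copy(),
            self.type_ids.copy(),
            self.type_names,
            self.box,
            self.step,
        )


@dataclass
class SimSettings:
    """Integration and ensemble parameters (DPD reduced units)."""

    dt: float = 0.01
    n_steps: int = 1000
    gamma: float = 4.5
    kT: float = 1.0
    ensemble: str = "NVT"
    target_pressure: float = WATER_PRESSURE
    barostat_tau: float = 1.0
    sample_every: int = 1000
    obs_every: int = 10
    equilibration_fraction: float = 0.125  # matches 5e5 of a 4e6-step production run
    seed: int = 0
    electrostatics: ElectrostaticSettings | None = None
    max_displacement: float = 0.5
    allow_any_density: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_steps < 1 or self.sample_every < 1:
            raise ValueError("dt, n_steps and sample_every must be positive")
        if self.ensemble not in ("NVT", "NPT"):
            raise ValueError("ensemble must be NVT or NPT")

    @property
    def sigma(self) -> float:
        return math.sqrt(2.0 * self.gamma * self.kT)

    @property
    def equilibration_steps(self) -> int:
        return int(self.n_steps * self.equilibration_fraction)


@dataclass(frozen=True)
class Composition:
    """Molecule counts, salt pairs and water filling one box."""

    box: float
    molecules: tuple[tuple[MoleculeTopology, int], ...] = ()
    salt: tuple[tuple[str, str, int], ...] = ()  # (cation, anion, n_pairs)
    n_water: int | None = None  # None: fill to the target density

    def bead_budget(self) -> int:
        n = sum(top.n_beads * count for top, count in self.molecules)
        n += sum(2 * pairs for _, _, pairs in self.salt)
        return n + (self.n_water or 0)

    def filled(self, density: float = 3.0) -> "Composition":
        """Fill the remaining bead budget with water at the target density."""
        total = int(round(density * self.box**3))
        solute = self.bead_budget() - (self.n_water or 0)
        n_water = total - solute
        if n_water < 0:
            raise EngineError("solute beads alone exceed the target density")
        return replace(self, n_water=n_water)

    @classmethod
    def water_box(cls, box: float, density: float = 3.0) -> "Composition":
        return cls(box=box).filled(density)


@dataclass
class System:
    """A composition compiled against a force field into flat arrays."""

    ff: ForceField
    box: float
    type_names: tuple[str, ...]
    type_ids: np.ndarray
    charges: np.ndarray  # per bead
    amp: np.ndarray  # (T, T) amplitudes
    rng: np.ndarray  # (T, T) cutoffs
    mol_ids: np.ndarray  # per bead; -1 for water/ions... (waters get own ids)
    mol_names: list[str]  # per molecule id
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_r0: np.ndarray
    ang_i: np.ndarray
    ang_j: np.ndarray
    ang_k: np.ndarray
    ang_t0: np.ndarray
    topologies: tuple[tuple[MoleculeTopology, int], ...]

    @property
    def n_beads(self) -> int:
        return self.type_ids.shape[0]

    @property
    def bonded(self) -> BondedTerms:
        return self.ff.bonded

    @property
    def max_cutoff(self) -> float:
        return float(self.rng.max()) if self.rng.size else 1.0

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())


def _pair_tables(ff: ForceField, type_names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    t = len(type_names)
    amp = np.zeros((t, t))
    rng = np.zeros((t, t))
    for i, b1 in enumerate(type_names):
        for j, b2 in enumerate(type_names):
            rec = ff.pair(b1, b2)  # raises MissingParameterError -> fail fast
            amp[i, j] = rec.amplitude
            rng[i, j] = rec.cutoff
    return amp, rng


def build_system(composition: Composition, ff: ForceField) -> System:
    """Expand a composition into per-bead arrays, failing fast on coverage."""
    comp = composition
    names: list[str] = []
    mol_ids: list[int] = []
    mol_names: list[str] = []
    bonds: list[tuple[int, int, float]] = []
    angles: list[tuple[int, int, int, float]] = []
    mol = 0
    for top, count in comp.molecules:
        top.validate_against(ff)
        for _ in range(count):
            base = len(names)
            names.extend(top.beads)
            mol_ids.extend([mol] * top.n_beads)
            mol_names.append(top.name)
            bonds.extend((base + i, base + j, r0) for i, j, r0 in top.bonds)
            angles.extend(
                (base + i, base + j, base + k, t0) for i, j, k, t0 in top.angles
            )
            mol += 1
    for cation, anion, pairs in comp.salt:
        for ion in (cation, anion):
            if ion not in ff.beads or not ff.beads[ion].is_ion:
                raise MissingParameterError(f"{ion!r} is not an ion bead of this force field")
        for _ in range(pairs):
            for ion in (cation, anion):
                names.append(ion)
                mol_ids.append(mol)
                mol_names.append(ion)
                mol += 1
    for _ in range(comp.n_water or 0):
        names.append(WATER)
        mol_ids.append(mol)
        mol_names.append(WATER)
        mol += 1
    if not names:
        raise EngineError("empty composition")
    type_names = tuple(sorted(set(names)))
    index = {n: i for i, n in enumerate(type_names)}
    type_ids = np.array([index[n] for n in names], dtype=np.int64)
    charges = np.array([ff.beads[n].charge for n in names], dtype=np.float64)
    amp, rng = _pair_tables(ff, type_names)
    b = np.array(bonds, dtype=np.float64).reshape(-1, 3)
    a = np.array(angles, dtype=np.float64).reshape(-1, 4)
    return System(
        ff=ff,
        box=comp.box,
        type_names=type_names,
        type_ids=type_ids,
        charges=charges,
        amp=amp,
        rng=rng,
        mol_ids=np.array(mol_ids, dtype=np.int64),
        mol_names=mol_names,
        bond_i=b[:, 0].astype(np.int64),
        bond_j=b[:, 1].astype(np.int64),
        bond_r0=b[:, 2].copy(),
        ang_i=a[:, 0].astype(np.int64),
        ang_j=a[:, 1].astype(np.int64),
        ang_k=a[:, 2].astype(np.int64),
        ang_t0=a[:, 3].copy(),
        topologies=comp.molecules,
    )


def initial_state(system: System, seed: int = 0, kT: float = 1.0) -> SimState:
    """Random initial configuration: molecules as bond-length random walks,
    water/ions uniform; Maxwell velocities with the net momentum zeroed."""
    rng = np.random.default_rng(seed)
    L = system.box
    n = system.n_beads
    pos = rng.random((n, 3)) * L
    # rebuild molecule beads as connected random walks so bonds start relaxed
    adj: dict[int, list[tuple[int, float]]] = {}
    for i, j, r0 in zip(system.bond_i, system.bond_j, system.bond_r0):
        adj.setdefault(int(i), []).append((int(j), float(r0)))
        adj.setdefault(int(j), []).append((int(i), float(r0)))
    seen: set[int] = set()
    for start in sorted(adj):
        if start in seen:
            continue
        seen.add(start)
        stack = [start]
        while stack:
            i = stack.pop()
            for j, r0 in adj.get(i, []):
                if j in seen:
                    continue
                seen.add(j)
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                pos[j] = (pos[i] + r0 * u) % L
                stack.append(j)
    vel = rng.normal(0.0, math.sqrt(kT), size=(n, 3))
    vel -= vel.mean(axis=0)
    return SimState(pos, vel, system.type_ids.copy(), system.type_names, L, 0)


# ---------------------------------------------------------------------------
# Forces


def _ncell(box: float, cutoff: float) -> int:
    return int(box / cutoff)


def _nonbonded(
    state: SimState,
    system: System,
    gamma: float,
    sigma: float,
    inv_sqrt_dt: float,
    salt: int,
    thermo: bool,
):
    cutoff = max(system.max_cutoff, 1.0)
    ncell = _ncell(state.box, cutoff)
    if ncell >= 3:
        head, nxt = _kernels.build_cells(state.positions, state.box, ncell)
        return _kernels.nonbonded_cells(
            state.positions, state.velocities, state.type_ids, system.amp,
            system.rng, state.box, ncell, head, nxt,
            gamma, sigma, inv_sqrt_dt, salt, thermo,
        )
    return _kernels.nonbonded_allpairs(
        state.positions, state.velocities, state.type_ids, system.amp,
        system.rng, state.box, gamma, sigma, inv_sqrt_dt, salt, thermo,
    )


def conservative_forces(state: SimState, ff: ForceField) -> tuple[np.ndarray, float]:
    """Soft-repulsion forces and scalar virial for an arbitrary state.

    Coincident bead pairs contribute zero force (the potential is finite at
    r=0 but the direction is undefined); a warning is emitted when this occurs.
    """
    amp, rng = _pair_tables(ff, state.type_names)
    cutoff = max(float(rng.max()), 1.0)
    ncell = _ncell(state.box, cutoff)
    if ncell >= 3:
        head, nxt = _kernels.build_cells(state.positions, state.box, ncell)
        F, vir, overlaps = _kernels.nonbonded_cells(
            state.positions, state.velocities, state.type_ids, amp, rng,
            state.box, ncell, head, nxt, 0.0, 0.0, 1.0, 0, False,
        )
    else:
        F, vir, overlaps = _kernels.nonbonded_allpairs(
            state.positions, state.velocities, state.type_ids, amp, rng,
            state.box, 0.0, 0.0, 1.0, 0, False,
        )
    if overlaps:
        warnings.warn(f"{overlaps} coincident bead pair(s): zero force assigned")
    return F, float(vir)


def conservative_energy(state: SimState, ff: ForceField) -> float:
    """O(N^2) soft-repulsion energy (reference/diagnostic use)."""
    amp, rng = _pair_tables(ff, state.type_names)
    pos, L, t = state.positions, state.box, state.type_ids
    d = pos[:, None, :] - pos[None, :, :]
    d -= L * np.round(d / L)
    r = np.sqrt((d**2).sum(-1))
    iu = np.triu_indices(len(pos), 1)
    rij = r[iu]
    a = amp[t[iu[0]], t[iu[1]]]
    rc = rng[t[iu[0]], t[iu[1]]]
    mask = rij < rc
    return float(
        (0.5 * a[mask] * rc[mask] * (1.0 - rij[mask] / rc[mask]) ** 2).sum()
    )


def bonded_forces(state: SimState, system: System) -> tuple[np.ndarray, float, float]:
    """Harmonic bond/angle forces; returns (forces, virial, energy)."""
    return _kernels.bonded_kernel(
        state.positions, state.box,
        system.bonded.bond_constant, system.bond_i, system.bond_j, system.bond_r0,
        system.bonded.angle_constant, system.ang_i, system.ang_j, system.ang_k,
        system.ang_t0,
    )


def bonded_energy(state: SimState, system: System) -> float:
    return bonded_forces(state, system)[2]


def _total_forces(state: SimState, system: System, settings: SimSettings, thermo=True):
    salt = _kernels.step_salt(settings.seed, state.step)
    F, vir, overlaps = _nonbonded(
        state, system, settings.gamma, settings.sigma,
        1.0 / math.sqrt(settings.dt), salt, thermo,
    )
    if overlaps:
        warnings.warn(f"{overlaps} coincident bead pair(s): zero force assigned")
    if system.bond_i.size or system.ang_i.size:
        Fb, vb, _ = bonded_forces(state, system)
        F += Fb
        vir += vb
    if settings.electrostatics is not None and np.any(system.charges):
        _, Fe = ewald_total(
            state.positions, system.charges, state.box, settings.electrostatics
        )
        F += Fe
    return F, vir


def integrate_step(
    state: SimState,
    system: System,
    settings: SimSettings,
    forces: np.ndarray | None = None,
) -> tuple[SimState, np.ndarray, float]:
    """One velocity-Verlet step; returns (new state, new forces, virial).

    The thermostat force is evaluated with the half-step velocities, the
    Groot-Warren flavour of velocity Verlet.  Deterministic given
    ``settings.seed`` and the step counter.
    """
    if forces is None:
        forces, _ = _total_forces(state, system, settings)
    new = state.copy()
    new.velocities += 0.5 * settings.dt * forces
    disp = settings.dt * np.abs(new.velocities).max()
    if disp > settings.max_displacement:
        raise InstabilityError(
            f"step displacement {disp:.3f} rc exceeds {settings.max_displacement}; "
            "reduce dt"
        )
    new.positions = (new.positions + settings.dt * new.velocities) % new.box
    new.step = state.step + 1
    F, vir = _total_forces(new, system, settings)
    new.velocities += 0.5 * settings.dt * F
    return new, F, vir


def _instant_tp(state: SimState, vir: float) -> tuple[float, float]:
    n = state.n_beads
    ke = 0.5 * float((state.velocities**2).sum())
    T = 2.0 * ke / (3 * n - 3)
    P = (n * T + vir / 3.0) / state.box**3
    return T, P


@dataclass
class TrajectoryFrame:
    step: int
    positions: np.ndarray
    box: float


@dataclass
class Trajectory:
    """Sampled frames plus the bead -> molecule identity map."""

    frames: list[TrajectoryFrame]
    bead_names: list[str]
    mol_ids: np.ndarray
    mol_names: list[str]  # indexed by molecule id
    observables: pd.DataFrame | None = None
    n_steps: int = 0
    tail_beads: frozenset[str] = frozenset()  # hydrophobic-core bead names

    def __post_init__(self) -> None:
        counts = np.bincount(self.mol_ids)
        if (counts == 0).any():
            raise EngineError("molecule id map must partition all beads")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def write_xyz(self, path: str | Path, molecule_map: str | Path | None = None) -> None:
        """Extended-XYZ dump; optionally a bead->molecule sidecar CSV."""
        lines: list[str] = []
        for fr in self.frames:
            lines.append(str(len(self.bead_names)))
            lines.append(f"step={fr.step} L={float(fr.box)!r}")
            for name, (x, y, z) in zip(self.bead_names, fr.positions):
                lines.append(f"{name} {float(x)!r} {float(y)!r} {float(z)!r}")
        Path(path).write_text("\n".join(lines) + "\n")
        if molecule_map is not None:
            rows = ["bead_index,molecule_id,molecule_name"]
            rows += [
                f"{i},{m},{self.mol_names[m]}"
                for i, m in enumerate(self.mol_ids)
            ]
            Path(molecule_map).write_text("\n".join(rows) + "\n")

    @classmethod
    def read_xyz(cls, path: str | Path, molecule_map: str | Path) -> "Trajectory":
        lines = Path(path).read_text().splitlines()
        frames: list[TrajectoryFrame] = []
        bead_names: list[str] = []
        i = 0
        while i < len(lines):
            n = int(lines[i])
            meta = dict(tok.split("=") for tok in lines[i + 1].split())
            block = lines[i + 2 : i + 2 + n]
            names = []
            pos = np.empty((n, 3))
            for k, ln in enumerate(block):
                parts = ln.split()
                names.append(parts[0])
                pos[k] = [float(p) for p in parts[1:4]]
            frames.append(
                TrajectoryFrame(int(meta["step"]), pos, float(meta["L"]))
            )
            bead_names = names
            i += 2 + n
        mm = pd.read_csv(molecule_map)
        mol_ids = mm["molecule_id"].to_numpy(dtype=np.int64)
        mol_names = (
            mm.drop_duplicates("molecule_id")
            .sort_values("molecule_id")["molecule_name"]
            .tolist()
        )
        steps = frames[-1].step if frames else 0
        return cls(frames, bead_names, mol_ids, mol_names, None, steps)


def run_simulation(
    composition: Composition,
    ff: ForceField,
    settings: SimSettings,
    density: float = 3.0,
) -> Trajectory:
    """Build, equilibrate and sample a DPD run; emits frames and observables."""
    system = build_system(composition, ff)
    if abs(system.net_charge) > 1e-9:
        raise EngineError(
            f"system carries net charge {system.net_charge:+g}; refusing to run"
        )
    actual = system.n_beads / composition.box**3
    if not settings.allow_any_density and abs(actual - density) > 0.02:
        raise EngineError(
            f"bead density {actual:.3f} differs from {density}; "
            "use Composition.filled() or allow_any_density"
        )
    if np.any(system.charges) and settings.electrostatics is None:
        settings = replace(settings, electrostatics=ElectrostaticSettings())
    state = initial_state(system, settings.seed, settings.kT)
    F, vir = _total_forces(state, system, settings)
    frames: list[TrajectoryFrame] = []
    obs: list[tuple[int, float, float, float]] = []
    for _ in range(settings.n_steps):
        state, F, vir = integrate_step(state, system, settings, F)
        if settings.ensemble == "NPT":
            _, P = _instant_tp(state, vir)
            mu = (
                1.0
                - settings.dt / settings.barostat_tau * (settings.target_pressure - P)
            ) ** (1.0 / 3.0)
            mu = min(max(mu, 0.99), 1.01)
            state.positions *= mu
            state.box *= mu
            state.positions %= state.box
        if state.step % settings.obs_every == 0:
            T, P = _instant_tp(state, vir)
            obs.append((state.step, T, P, state.box))
        if state.step % settings.sample_every == 0:
            frames.append(
                TrajectoryFrame(state.step, state.positions.copy(), state.box)
            )
    observables = pd.DataFrame(obs, columns=["step", "temperature", "pressure", "box"])
    tails = frozenset().union(*(t.tail_beads for t, _ in composition.molecules)) \
        if composition.molecules else frozenset()
    return Trajectory(
        frames, [system.type_names[t] for t in system.type_ids],
        system.mol_ids.copy(), list(system.mol_names), observables,
        settings.n_steps, tails,
    )


@dataclass(frozen=True)
class ObservableSummary:
    temperature: float
    pressure: float
    density: float
    n_samples: int


def measure_observables(
    traj: Trajectory, discard_steps: int | None = None
) -> ObservableSummary:
    """Average temperature/pressure over the post-equilibration window."""
    if traj.observables is None or traj.observables.empty:
        raise EngineError("trajectory carries no observable samples")
    if discard_steps is None:
        discard_steps = int(traj.n_steps * 0.125)
    window = traj.observables[traj.observables["step"] > discard_steps]
    if window.empty:
        raise EngineError("observable window is empty after discarding equilibration")
    n_beads = len(traj.bead_names)
    mean_box = float(window["box"].mean())
    return ObservableSummary(
        temperature=float(window["temperature"].mean()),
        pressure=float(window["pressure"].mean()),
        density=n_beads / mean_box**3,
        n_samples=len(window),
    )
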