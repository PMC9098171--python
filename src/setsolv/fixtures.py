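"""Deterministic synthetic inputs for the analysis stages.

Two generators: geometric trajectories with planted micelles (testing the
clustering and CMC pipeline without running a simulation) and Setschenow
datasets with planted model parameters (testing the fitting stack as exact
inverse problems).  Micelle fixtures are geometric, not physical — tail beads
of one planted micelle are packed inside a ball tight enough to guarantee
single-linkage connectivity at the contact cutoff, and monomers are kept well
clear of every micelle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Trajectory, TrajectoryFrame
from .forcefield import BeadSpec, BondedTerms, ForceField, MoleculeTopology, PairInteraction
from .setschenow import CMCSeries, Eq6Model, predict_ks

__all__ = [
    "MicelleFixtureSpec",
    "KsFixtureSpec",
    "generate_micelle_trajectory",
    "generate_ks_dataset",
    "model_amphiphile",
]


def model_amphiphile(
    tail_water_repulsion: float = 80.0,
    head_water_repulsion: float = 25.0,
    n_tail: int = 3,
) -> tuple[ForceField, MoleculeTopology]:
    """A minimal amphiphile model (head bead H, tail beads TL, water W).

    Head and like-bead repulsions sit at the water-water baseline so the head
    stays solvated; the tail-water amplitude is the micellization driver.
    Used for desk-scale self-assembly runs and fixtures.
    """
    base = 25.0
    beads = [
        BeadSpec("W", 0, "water"),
        BeadSpec("H", 0, "head"),
        BeadSpec("TL", 0, "tail"),
    ]
    pairs = [
        PairInteraction(("W", "W"), base, 1.0),
        PairInteraction(("H", "H"), base, 1.0),
        PairInteraction(("TL", "TL"), base, 1.0),
        PairInteraction(("H", "W"), head_water_repulsion, 1.0),
        PairInteraction(("H", "TL"), 50.0, 1.0),
        PairInteraction(("TL", "W"), tail_water_repulsion, 1.0),
    ]
    ff = ForceField(beads, pairs, BondedTerms())
    names = ("H",) + ("TL",) * n_tail
    bonds = tuple((i, i + 1, 0.5) for i in range(n_tail))
    angles = tuple(
        (i, i + 1, i + 2, math.pi) for i in range(n_tail - 1)
    )
    top = MoleculeTopology(
        name="HT" + str(n_tail),
        beads=names,
        bonds=bonds,
        angles=angles,
        head_beads=frozenset({"H"}),
        tail_beads=frozenset({"TL"}),
    )
    return ff, top


@dataclass(frozen=True)
class MicelleFixtureSpec:
    """Geometry of a planted-micelle trajectory."""

    box: float
    n_micelles: int
    size_range: tuple[int, int] = (20, 30)
    micelle_sizes: tuple[int, ...] | None = None  # overrides size_range
    n_monomers: int = 10
    topology: MoleculeTopology | None = None  # default: model_amphiphile()[1]
    jitter: float = 0.05
    contact_cutoff: float = 1.0
    seed: int = 0

    def resolved_topology(self) -> MoleculeTopology:
        return self.topology if self.topology is not None else model_amphiphile()[1]

    def sizes(self, rng: np.random.Generator) -> list[int]:
        if self.micelle_sizes is not None:
            if len(self.micelle_sizes) != self.n_micelles:
                raise ValueError("micelle_sizes length must equal n_micelles")
            return list(self.micelle_sizes)
        lo, hi = self.size_range
        if not (2 <= lo <= hi):
            raise ValueError("micelle size range must satisfy 2 <= lo <= hi")
        return [int(rng.integers(lo, hi + 1)) for _ in range(self.n_micelles)]


def _poisson_disk(
    rng: np.random.Generator, n: int, box: float, min_sep: float, max_tries: int = 20000
) -> np.ndarray:
    """Periodic random points with a minimum pairwise separation."""
    pts: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(pts) == n:
            break
        cand = rng.random(3) * box
        ok = True
        for p in pts:
            d = cand - p
            d -= box * np.round(d / box)
            if np.dot(d, d) < min_sep**2:
                ok = False
                break
        if ok:
            pts.append(cand)
    if len(pts) < n:
        raise ValueError(
            f"could not place {n} centers at separation {min_sep} in box {box}"
        )
    return np.array(pts)


def generate_micelle_trajectory(
    spec: MicelleFixtureSpec, n_frames: int = 5
) -> tuple[Trajectory, np.ndarray]:
    """Trajectory with planted aggregates plus ground-truth labels.

    Tail beads of a planted micelle lie within ``contact_cutoff/2`` of its
    center, so every tail-bead pair of the micelle is within the cutoff (a
    connectivity clique); monomers sit at least 3 rc from every micelle
    center and one cutoff from each other.  Returns the trajectory and the
    per-molecule aggregate label (monomers get labels -1).
    """
    rng = np.random.default_rng(spec.seed)
    top = spec.resolved_topology()
    sizes = spec.sizes(rng)
    core_r = 0.5 * spec.contact_cutoff
    min_center_sep = 2.0 * (core_r + 1.5) + 0.5  # micelle shells must not touch
    if spec.n_micelles and min_center_sep > spec.box / 2:
        raise ValueError("box too small for non-overlapping micelles")
    centers = (
        _poisson_disk(rng, spec.n_micelles, spec.box, min_center_sep)
        if spec.n_micelles
        else np.empty((0, 3))
    )

    tail_local = top.tail_indices()
    if not tail_local:
        raise ValueError("fixture topology has no tail beads")
    n_mol = sum(sizes) + spec.n_monomers
    labels = np.empty(n_mol, dtype=int)
    bead_names: list[str] = []
    mol_ids: list[int] = []
    mol_names: list[str] = []
    placements: list[tuple[int, np.ndarray]] = []  # (molecule, anchor)
    mol = 0
    for m, size in enumerate(sizes):
        for _ in range(size):
            labels[mol] = m
            placements.append((mol, centers[m]))
            mol += 1
    # monomer anchors: clear of all micelle shells and of each other
    mono_anchor = []
    for _ in range(spec.n_monomers):
        for _try in range(20000):
            cand = rng.random(3) * spec.box
            d = cand - centers if len(centers) else np.empty((0, 3))
            if len(d):
                d -= spec.box * np.round(d / spec.box)
                if (np.linalg.norm(d, axis=1) < 3.0 + core_r).any():
                    continue
            far = True
            for p in mono_anchor:
                dd = cand - p
                dd -= spec.box * np.round(dd / spec.box)
                if np.linalg.norm(dd) < spec.contact_cutoff + 2.5:
                    far = False
                    break
            if far:
                mono_anchor.append(cand)
                break
        else:
            raise ValueError("could not place monomers clear of micelles")
        labels[mol] = -1
        placements.append((mol, mono_anchor[-1]))
        mol += 1
    for m, _ in placements:
        bead_names.extend(top.beads)
        mol_ids.extend([m] * top.n_beads)
        mol_names.append(top.name)

    n_beads = len(bead_names)
    frames = []
    for f in range(n_frames):
        pos = np.empty((n_beads, 3))
        i = 0
        for (m, anchor) in placements:
            for local, bead in enumerate(top.beads):
                if local in tail_local:
                    # random point in the core ball: every tail pair of the
                    # micelle stays strictly within the contact cutoff
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    radius = 0.9 * core_r * rng.random() ** (1 / 3)
                    p = anchor + radius * u
                else:
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    p = anchor + (core_r + 0.8) * u + rng.normal(0.0, spec.jitter, 3)
                pos[i] = np.mod(p, spec.box)
                i += 1
        frames.append(TrajectoryFrame(step=(f + 1) * 1000, positions=pos, box=spec.box))
    traj = Trajectory(
        frames=frames,
        bead_names=bead_names,
        mol_ids=np.array(mol_ids, dtype=np.int64),
        mol_names=mol_names,
        observables=None,
        n_steps=(n_frames + 1) * 1000,
        tail_beads=frozenset(top.tail_beads),
    )
    return traj, labels


@dataclass(frozen=True)
class KsFixtureSpec:
    """Planted separable model plus sampling grid for synthetic k_s data."""

    model: Eq6Model
    salts: tuple[tuple[str, str], ...]  # (cation, anion)
    surfactants: tuple[str, ...] = ()
    concentrations: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    cmc0: float = 0.02  # mol/L, zero-salt reference CMC
    noise_sigma: float = 0.0  # lognormal sigma on CMC values
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if 0.0 not in self.concentrations:
            raise ValueError("concentration grid must include 0")

    def resolved_surfactants(self) -> tuple[str, ...]:
        return self.surfactants or tuple(self.model.surfactants)


def generate_ks_dataset(
    spec: KsFixtureSpec, outdir: str | Path | None = None
) -> tuple[pd.DataFrame, dict[tuple[str, str, str], CMCSeries]]:
    """Synthetic k_s table and CMC-salt series from a planted model.

    CMC series follow ln(CMC/CMC0) = -k_s C with k_s from the planted model;
    lognormal noise of width ``noise_sigma`` multiplies each CMC.  Output
    files (when ``outdir`` is given) use the standard experimental-table and
    series CSV formats.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    series: dict[tuple[str, str, str], CMCSeries] = {}
    for surf in spec.resolved_surfactants():
        for cation, anion in spec.salts:
            ks = predict_ks(spec.model, surf, cation, anion)
            c = np.asarray(spec.concentrations, dtype=float)
            cmc = spec.cmc0 * np.exp(-ks * c)
            if spec.noise_sigma > 0:
                cmc = cmc * rng.lognormal(0.0, spec.noise_sigma, size=len(c))
            ser = CMCSeries(surf, tuple(c), tuple(cmc), cmc0=spec.cmc0)
            series[(surf, cation, anion)] = ser
            rows.append(
                {
                    "surfactant": surf,
                    "cation": cation,
                    "anion": anion,
                    "ks": ks,
                    "source_flag": "monovalent",
                }
            )
    table = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "ks_table.csv", index=False)
        for (surf, cation, anion), ser in series.items():
            pd.DataFrame(
                {"c_salt": ser.concentrations, "cmc": ser.cmcs}
            ).to_csv(outdir / f"cmc_{surf}_{cation}{anion}.csv", index=False)
    return table, series
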