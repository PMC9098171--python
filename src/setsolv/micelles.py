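"""Aggregate identification, aggregation-number distributions and the CMC.

Surfactant molecules are clustered frame by frame with single-linkage tail
contact: two molecules join the same aggregate when any pair of their
hydrophobic-tail beads lies within the contact cutoff under minimum image,
and the transitive closure is taken.  Pooling aggregate sizes over the
post-equilibration frames gives the population distribution P(N); its
interior minimum N_cut separates free surfactant (monomers plus submicellar
aggregates, N < N_cut) from micelles.  The critical micelle concentration is
the mean free-surfactant count converted to mol/L with the volume mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .engine import Trajectory, TrajectoryFrame
from .forcefield import TAIL_BEADS
from .units import MOLAR_DPD_VOLUME_L, molar_concentration

__all__ = [
    "AggregateDistribution",
    "CmcEstimate",
    "cluster_frame",
    "aggregation_distribution",
    "find_ncut",
    "cmc_from_trajectory",
    "average_cmc",
]

DEFAULT_CONTACT_CUTOFF = 1.0
DEFAULT_NCUT_FALLBACK = 10


def _surfactant_mask(traj: Trajectory, tail_beads: frozenset[str]) -> np.ndarray:
    """Molecule ids of surfactants: molecules owning at least one tail bead
    (water and ion beads carry no tails)."""
    names = np.asarray(traj.bead_names)
    has_tail = np.isin(names, list(tail_beads))
    return np.unique(traj.mol_ids[has_tail])


def _resolve_tails(traj: Trajectory, tail_beads) -> frozenset[str]:
    if tail_beads is not None:
        return frozenset(tail_beads)
    return traj.tail_beads or TAIL_BEADS


def cluster_frame(
    frame: TrajectoryFrame,
    traj: Trajectory,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    tail_beads: frozenset[str] | set[str] | None = None,
) -> list[np.ndarray]:
    """Partition surfactant molecules of one frame into aggregates.

    Returns a list of aggregates, each an array of molecule ids.  Single
    linkage on tail-bead contact within ``cutoff`` (rc, minimum image).
    ``tail_beads`` defaults to the trajectory's own tail set, falling back to
    the packaged force field's tail species.
    """
    if cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    tail_beads = _resolve_tails(traj, tail_beads)
    surf_mols = _surfactant_mask(traj, tail_beads)
    if surf_mols.size == 0:
        raise ValueError("frame contains no surfactant molecules")
    names = np.asarray(traj.bead_names)
    tail_idx = np.flatnonzero(np.isin(names, list(tail_beads)))
    mol_of_tail = traj.mol_ids[tail_idx]
    remap = {m: i for i, m in enumerate(surf_mols)}
    n_mol = len(surf_mols)
    pos = np.mod(frame.positions[tail_idx], frame.box)
    tree = cKDTree(pos, boxsize=frame.box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        mi = np.array([remap[m] for m in mol_of_tail[pairs[:, 0]]])
        mj = np.array([remap[m] for m in mol_of_tail[pairs[:, 1]]])
        adj = coo_matrix((np.ones(len(mi)), (mi, mj)), shape=(n_mol, n_mol))
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n_mol)
    return [surf_mols[labels == lab] for lab in np.unique(labels)]


@dataclass
class AggregateDistribution:
    """Histogram of aggregation numbers.

    ``sizes`` is the (sorted) support axis; ``counts`` the matching weights.
    With molecule weighting, an aggregate of size N contributes N to its bin
    (so the per-frame sum of N*count(N)/n_frames is the number of surfactant
    molecules); with aggregate weighting it contributes 1.
    """

    sizes: np.ndarray
    counts: np.ndarray
    n_frames: int = 1
    smoothing_window: int = 1
    weighting: str = "molecule"
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.sizes.size == 0:
            raise ValueError("empty distribution")
        if (self.counts < 0).any():
            raise ValueError("P(N) must be non-negative")
        order = np.argsort(self.sizes)
        self.sizes = self.sizes[order]
        self.counts = self.counts[order]

    @classmethod
    def from_counts(
        cls, counts: dict[int, float], **kw
    ) -> "AggregateDistribution":
        sizes = np.array(sorted(counts))
        return cls(sizes, np.array([counts[s] for s in sizes], dtype=float), **kw)

    @property
    def population(self) -> np.ndarray:
        """Normalized P(N) on the support axis."""
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts

    def smoothed(self) -> np.ndarray:
        """Moving average of the counts over consecutive support points."""
        w = max(int(self.smoothing_window), 1)
        if w == 1:
            return self.counts.copy()
        kernel = np.ones(w) / w
        padded = np.pad(self.counts, w // 2, mode="edge")
        return np.convolve(padded, kernel, mode="valid")[: len(self.counts)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"N": self.sizes, "count": self.counts, "P": self.population}
        )


def aggregation_distribution(
    traj: Trajectory,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    tail_beads: frozenset[str] | set[str] | None = None,
    discard_steps: int | None = None,
    smoothing_window: int = 3,
    weighting: str = "molecule",
) -> AggregateDistribution:
    """Pool aggregate sizes over post-equilibration frames into P(N).

    The support axis is dense (1..max observed size) so depleted regions show
    up as zero-count bins.  ``discard_steps`` defaults to 1/8 of the run, the
    production equilibration fraction scaled to the run length.
    """
    if weighting not in ("molecule", "aggregate"):
        raise ValueError("weighting must be 'molecule' or 'aggregate'")
    if discard_steps is None:
        discard_steps = int(traj.n_steps * 0.125)
    frames = [f for f in traj.frames if f.step > discard_steps]
    if not frames:
        raise ValueError("no frames left after equilibration discard")
    warns: list[str] = []
    if len(frames) < 10:
        warns.append(f"only {len(frames)} usable frames; P(N) may be noisy")
    tally: dict[int, float] = {}
    for fr in frames:
        for agg in cluster_frame(fr, traj, cutoff, tail_beads):
            n = len(agg)
            tally[n] = tally.get(n, 0.0) + (n if weighting == "molecule" else 1.0)
    nmax = max(tally)
    sizes = np.arange(1, nmax + 1)
    counts = np.array([tally.get(int(s), 0.0) for s in sizes])
    return AggregateDistribution(
        sizes, counts, n_frames=len(frames),
        smoothing_window=smoothing_window, weighting=weighting,
        warnings_=warns,
    )


def find_ncut(
    dist: AggregateDistribution, fallback: int = DEFAULT_NCUT_FALLBACK
) -> int:
    """N_cut at the minimum of P(N) between the monomer and micelle modes.

    Operates on the smoothed counts; ties break toward smaller N.  When the
    distribution has no interior minimum (monotone or single-mode P) the
    configured fallback is returned with a warning.
    """
    p = dist.smoothed()
    sizes = dist.sizes
    if len(sizes) < 3:
        warnings.warn(f"distribution too narrow for a minimum; N_cut={fallback}")
        return fallback
    # local maxima of the smoothed counts
    maxima = [
        i
        for i in range(len(p))
        if (i == 0 or p[i] > p[i - 1]) and (i == len(p) - 1 or p[i] >= p[i + 1])
        and p[i] > 0
    ]
    if len(maxima) < 2:
        warnings.warn(f"no interior minimum in P(N); falling back to N_cut={fallback}")
        return fallback
    lo, hi = maxima[0], maxima[-1]
    interior = np.arange(lo + 1, hi)
    if interior.size == 0:
        warnings.warn(f"modes are adjacent; falling back to N_cut={fallback}")
        return fallback
    best = interior[np.argmin(p[interior])]  # argmin returns first tie -> smaller N
    return int(sizes[best])


@dataclass
class CmcEstimate:
    """Free-surfactant concentration of one run (the CMC proxy)."""

    n_cut: int
    cmc_molar: float
    free_count_mean: float
    n_surfactants: int
    per_frame_free: np.ndarray
    flags: list[str] = field(default_factory=list)


def cmc_from_trajectory(
    traj: Trajectory,
    n_cut: int,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    tail_beads: frozenset[str] | set[str] | None = None,
    discard_steps: int | None = None,
    molar_dpd_volume: float = MOLAR_DPD_VOLUME_L,
) -> CmcEstimate:
    """CMC as the mean concentration of molecules in aggregates with N < N_cut."""
    if n_cut < 2:
        raise ValueError("N_cut must be at least 2")
    tail_beads = _resolve_tails(traj, tail_beads)
    if discard_steps is None:
        discard_steps = int(traj.n_steps * 0.125)
    frames = [f for f in traj.frames if f.step > discard_steps]
    if not frames:
        raise ValueError("no frames left after equilibration discard")
    free = []
    max_agg = 0
    for fr in frames:
        aggs = cluster_frame(fr, traj, cutoff, tail_beads)
        max_agg = max(max_agg, max(len(a) for a in aggs))
        free.append(sum(len(a) for a in aggs if len(a) < n_cut))
    free_arr = np.array(free, dtype=float)
    n_surf = len(_surfactant_mask(traj, tail_beads))
    flags: list[str] = []
    if n_cut > max_agg:
        flags.append(
            "N_cut exceeds the largest observed aggregate; CMC equals the "
            "total surfactant concentration"
        )
    mean_free = float(free_arr.mean())
    if mean_free == 0.0:
        flags.append("no free surfactant observed; CMC = 0")
    box = frames[0].box
    return CmcEstimate(
        n_cut=n_cut,
        cmc_molar=molar_concentration(mean_free, box, molar_dpd_volume),
        free_count_mean=mean_free,
        n_surfactants=n_surf,
        per_frame_free=free_arr,
        flags=flags,
    )


def average_cmc(estimates: list[CmcEstimate]) -> float:
    """Mean CMC over runs at different surfactant loadings."""
    if not estimates:
        raise ValueError("no estimates to average")
    return float(np.mean([e.cmc_molar for e in estimates]))
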