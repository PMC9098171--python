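"""DPD force field: pairwise soft repulsions, bonded terms, molecule topologies.

The conservative interaction between bead types ``i`` and ``j`` is the linear
soft repulsion ``F(r) = a_ij (1 - r/R_ij) r_hat`` for ``r < R_ij``, so the
chemistry of the model lives entirely in the table of amplitudes ``a_ij``
(in kBT) and ranges ``R_ij`` (in rc).  The shipped table covers ten bead
species (water W, tail beads T/T2/C2, head beads AM3/OH/OH'/OH2/AC' and the
ethylene-oxide bead EO); primed names are serialized as ``OHp``/``ACp``.

Monovalent salt ions are modelled as charged water beads: an ion bead carries
charge +-1 and inherits every interaction of W unless an explicit ion-tail
override is registered.  Overriding those ion-tail amplitudes is the handle by
which salting-out specificity enters the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "BeadSpec",
    "PairInteraction",
    "BondedTerms",
    "MoleculeTopology",
    "ForceField",
    "MissingParameterError",
    "ForceFieldError",
    "load_default_forcefield",
    "load_topology",
    "builtin_topology",
    "make_ion",
    "TAIL_BEADS",
    "HEAD_BEADS",
    "ION_SCREEN_RANGE",
]

#: Bead species forming the hydrophobic tail / hydrophilic head of the
#: shipped surfactants.
TAIL_BEADS = frozenset({"T", "T2", "C2"})
HEAD_BEADS = frozenset({"AM3", "OH", "OHp", "OH2", "ACp"})

#: Range over which ion-tail repulsion amplitudes were screened (kBT).
ION_SCREEN_RANGE = (35.0, 150.0)

WATER = "W"

# Accept the unicode prime spellings on input; serialize with the ASCII 'p'.
_NAME_ALIASES = {
    "OH′": "OHp",
    "AC′": "ACp",
    "OH'": "OHp",
    "AC'": "ACp",
}


def normalize_bead_name(name: str) -> str:
    return _NAME_ALIASES.get(name.strip(), name.strip())


class ForceFieldError(ValueError):
    """Malformed or inconsistent force-field input."""


class MissingParameterError(KeyError):
    """A bead pair has no interaction parameters and no fallback rule."""


@dataclass(frozen=True)
class BeadSpec:
    """One bead species: label, integer valence and chemical role."""

    name: str
    charge: int = 0
    role: str = "water"

    _ROLES = ("water", "tail", "head", "cation", "anion")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ForceFieldError(f"unknown bead role {self.role!r}")
        if self.charge not in (-1, 0, 1):
            raise ForceFieldError("bead charge must be -1, 0 or +1")
        if (self.role == "cation") != (self.charge == 1) and self.role == "cation":
            raise ForceFieldError("cation beads must carry charge +1")
        if self.role == "anion" and self.charge != -1:
            raise ForceFieldError("anion beads must carry charge -1")

    @property
    def is_ion(self) -> bool:
        return self.role in ("cation", "anion")


@dataclass(frozen=True)
class PairInteraction:
    """Symmetric pair record: repulsion amplitude (kBT) and cutoff (rc)."""

    beads: tuple[str, str]
    amplitude: float
    cutoff: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ForceFieldError(f"negative amplitude for pair {self.beads}")
        if self.cutoff <= 0:
            raise ForceFieldError(f"non-positive cutoff for pair {self.beads}")


@dataclass(frozen=True)
class BondedTerms:
    """Global bonded-force constants: kb (kBT/rc^2) and ka (kBT/rad^2)."""

    bond_constant: float = 150.0
    angle_constant: float = 5.0

    def __post_init__(self) -> None:
        if self.bond_constant <= 0:
            raise ForceFieldError("bond constant must be positive")
        if self.angle_constant < 0:
            raise ForceFieldError("angle constant must be non-negative")


def _key(b1: str, b2: str) -> tuple[str, str]:
    return (b1, b2) if b1 <= b2 else (b2, b1)


def make_ion(name: str, charge: int) -> BeadSpec:
    """An ion bead: a charged clone of the water bead."""
    if charge not in (-1, 1):
        raise ForceFieldError("only monovalent ions are supported")
    return BeadSpec(name, charge, "cation" if charge > 0 else "anion")


class ForceField:
    """Immutable-by-convention container of bead specs and pair interactions.

    Lookups are symmetric.  For ion beads without an explicit record the
    interaction of water against the partner is returned (ions are charged
    water beads); any other absent pair raises :class:`MissingParameterError`
    so that systems are never built on invented parameters.
    """

    def __init__(
        self,
        beads: Iterable[BeadSpec],
        pairs: Iterable[PairInteraction],
        bonded: BondedTerms | None = None,
    ) -> None:
        self.beads: dict[str, BeadSpec] = {}
        for spec in beads:
            if spec.name in self.beads:
                raise ForceFieldError(f"duplicate bead name {spec.name!r}")
            self.beads[spec.name] = spec
        self._pairs: dict[tuple[str, str], PairInteraction] = {}
        for rec in pairs:
            k = _key(*rec.beads)
            if k in self._pairs:
                raise ForceFieldError(f"duplicate pair {k}")
            self._pairs[k] = rec
        self.bonded = bonded or BondedTerms()

    # -- lookups ---------------------------------------------------------

    def _resolve(self, name: str) -> str:
        """Map an ion bead to its water proxy for fallback lookups."""
        spec = self.beads.get(name)
        if spec is not None and spec.is_ion:
            return WATER
        return name

    def pair(self, b1: str, b2: str) -> PairInteraction:
        b1, b2 = normalize_bead_name(b1), normalize_bead_name(b2)
        for name in (b1, b2):
            if name not in self.beads:
                raise MissingParameterError(f"unknown bead {name!r}")
        rec = self._pairs.get(_key(b1, b2))
        if rec is not None:
            return rec
        # ion-as-water fallback
        p1, p2 = self._resolve(b1), self._resolve(b2)
        if (p1, p2) != (b1, b2):
            rec = self._pairs.get(_key(p1, p2))
            if rec is not None:
                return PairInteraction((b1, b2), rec.amplitude, rec.cutoff)
        raise MissingParameterError(
            f"no interaction parameters for pair ({b1}, {b2})"
        )

    def has_pair(self, b1: str, b2: str) -> bool:
        try:
            self.pair(b1, b2)
            return True
        except MissingParameterError:
            return False

    @property
    def explicit_pairs(self) -> list[PairInteraction]:
        return list(self._pairs.values())

    @property
    def max_cutoff(self) -> float:
        return max(p.cutoff for p in self._pairs.values())

    # -- derived force fields -------------------------------------------

    def with_beads(self, *specs: BeadSpec) -> "ForceField":
        """A new force field with additional bead species (e.g. ions)."""
        return ForceField(
            list(self.beads.values()) + list(specs),
            self._pairs.values(),
            self.bonded,
        )

    def with_ion_overrides(
        self,
        overrides: Mapping[tuple[str, str], float],
        allow_out_of_range: bool = False,
        allow_nontail: bool = False,
    ) -> "ForceField":
        """A new force field with ion-tail repulsion amplitudes replaced.

        ``overrides`` maps ``(ion name, tail bead name)`` to an amplitude in
        kBT.  The cutoff of an overridden pair is inherited from the
        corresponding water-tail pair (only amplitudes are varied, with the
        same range as water).  Amplitudes outside the screened range
        ``[35, 150]`` kBT require ``allow_out_of_range=True``; overriding a
        non-tail partner (the head/water screening mode) requires
        ``allow_nontail=True``.
        """
        new_pairs = dict(self._pairs)
        lo, hi = ION_SCREEN_RANGE
        for (ion, partner), amplitude in overrides.items():
            ion = normalize_bead_name(ion)
            partner = normalize_bead_name(partner)
            spec = self.beads.get(ion)
            if spec is None or not spec.is_ion:
                raise ForceFieldError(f"override target {ion!r} is not an ion bead")
            if partner not in self.beads:
                raise ForceFieldError(f"unknown partner bead {partner!r}")
            if partner not in TAIL_BEADS and not allow_nontail:
                raise ForceFieldError(
                    f"override of non-tail partner {partner!r} requires "
                    "allow_nontail=True"
                )
            if not (lo <= amplitude <= hi) and not allow_out_of_range:
                raise ForceFieldError(
                    f"amplitude {amplitude} outside screened range {ION_SCREEN_RANGE}; "
                    "pass allow_out_of_range=True to force"
                )
            cutoff = self.pair(WATER, partner).cutoff
            k = _key(ion, partner)
            new_pairs[k] = PairInteraction(k, float(amplitude), cutoff)
        return ForceField(self.beads.values(), new_pairs.values(), self.bonded)

    # -- serialization ---------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        lines = ["bead1\tbead2\ta\tR"]
        for (b1, b2), rec in self._pairs.items():
            lines.append(f"{b1}\t{b2}\t{rec.amplitude!r}\t{rec.cutoff!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(
        cls,
        path_or_text: str | Path,
        beads: Iterable[BeadSpec] | None = None,
        bonded: BondedTerms | None = None,
    ) -> "ForceField":
        """Parse a pair table with columns ``bead1 bead2 a R``."""
        if isinstance(path_or_text, Path) or "\n" not in str(path_or_text):
            text = Path(path_or_text).read_text()
        else:
            text = str(path_or_text)
        lines = text.splitlines()
        if not lines or [c.strip() for c in lines[0].split("\t")] != [
            "bead1",
            "bead2",
            "a",
            "R",
        ]:
            raise ForceFieldError("force-field TSV must have header 'bead1 bead2 a R'")
        pairs: dict[tuple[str, str], PairInteraction] = {}
        names: set[str] = set()
        for lineno, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ForceFieldError(f"line {lineno}: expected 4 columns, got {len(cols)}")
            b1, b2 = normalize_bead_name(cols[0]), normalize_bead_name(cols[1])
            try:
                a, r = float(cols[2]), float(cols[3])
            except ValueError as exc:
                raise ForceFieldError(f"line {lineno}: non-numeric a/R field") from exc
            k = _key(b1, b2)
            if k in pairs:
                raise ForceFieldError(f"line {lineno}: duplicate pair {k}")
            pairs[k] = PairInteraction(k, a, r)
            names.update(k)
        if beads is None:
            beads = [
                BeadSpec(
                    n,
                    0,
                    "tail" if n in TAIL_BEADS else "head" if n in HEAD_BEADS else "water",
                )
                for n in sorted(names)
            ]
        return cls(beads, pairs.values(), bonded)


def load_default_forcefield(source: str | Path = "builtin") -> ForceField:
    """The shipped ten-species interaction table, or a user TSV."""
    if source == "builtin":
        text = (
            resources.files("setsolv.data").joinpath("forcefield_pairs.tsv").read_text()
        )
        return ForceField.from_tsv(text)
    return ForceField.from_tsv(Path(source))


# ---------------------------------------------------------------------------
# Molecule topologies


@dataclass(frozen=True)
class MoleculeTopology:
    """Bead sequence plus bonded structure of one molecule.

    ``bonds`` are ``(i, j, r0)`` with the equilibrium length in rc; ``angles``
    are ``(i, j, k, theta0)`` with j the apex and theta0 in radians.
    """

    name: str
    beads: tuple[str, ...]
    bonds: tuple[tuple[int, int, float], ...] = ()
    angles: tuple[tuple[int, int, int, float], ...] = ()
    head_beads: frozenset[str] = frozenset()
    tail_beads: frozenset[str] = frozenset()
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        n = len(self.beads)
        if n == 0:
            raise ForceFieldError(f"topology {self.name!r} has no beads")
        for i, j, r0 in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ForceFieldError(f"{self.name}: invalid bond ({i},{j})")
            if r0 <= 0:
                raise ForceFieldError(f"{self.name}: bond r0 must be positive")
        for i, j, k, theta0 in self.angles:
            if len({i, j, k}) != 3 or not all(0 <= x < n for x in (i, j, k)):
                raise ForceFieldError(f"{self.name}: invalid angle ({i},{j},{k})")
            if not (0 < theta0 <= math.pi):
                raise ForceFieldError(f"{self.name}: theta0 must be in (0, pi]")
        if n > 1:
            # bond graph must be connected
            parent = list(range(n))

            def find(x: int) -> int:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for i, j, _ in self.bonds:
                parent[find(i)] = find(j)
            if len({find(i) for i in range(n)}) != 1:
                raise ForceFieldError(f"{self.name}: bond graph is not connected")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def validate_against(self, ff: ForceField) -> None:
        """Fail fast if any bead (or bead pair) cannot be parameterized."""
        for b in self.beads:
            if b not in ff.beads:
                raise MissingParameterError(f"{self.name}: unknown bead {b!r}")
        species = set(self.beads) | {WATER}
        for b1 in species:
            for b2 in species:
                ff.pair(b1, b2)

    def tail_indices(self) -> list[int]:
        return [i for i, b in enumerate(self.beads) if b in self.tail_beads]


def load_topology(path: str | Path) -> MoleculeTopology:
    """Read a molecule topology from its YAML config."""
    data = yaml.safe_load(Path(path).read_text())
    return _topology_from_dict(data)


def _topology_from_dict(data: dict) -> MoleculeTopology:
    try:
        beads = tuple(normalize_bead_name(b) for b in data["beads"])
        bonds = tuple(
            (int(b["i"]), int(b["j"]), float(b["r0"])) for b in data.get("bonds", [])
        )
        angles = tuple(
            (
                int(a["i"]),
                int(a["j"]),
                int(a["k"]),
                math.radians(float(a["theta0_deg"])),
            )
            for a in data.get("angles", [])
        )
        return MoleculeTopology(
            name=str(data["name"]),
            beads=beads,
            bonds=bonds,
            angles=angles,
            head_beads=frozenset(
                normalize_bead_name(b) for b in data.get("head_beads", [])
            ),
            tail_beads=frozenset(
                normalize_bead_name(b) for b in data.get("tail_beads", [])
            ),
            molar_mass=data.get("molar_mass"),
        )
    except (KeyError, TypeError) as exc:
        raise ForceFieldError(f"malformed topology config: {exc}") from exc


def builtin_topology(name: str) -> MoleculeTopology:
    """One of the shipped (approximate) surfactant topologies."""
    try:
        text = (
            resources.files("setsolv.data")
            .joinpath(f"topologies/{name}.yaml")
            .read_text()
        )
    except FileNotFoundError as exc:
        raise ForceFieldError(f"no builtin topology named {name!r}") from exc
    return _topology_from_dict(yaml.safe_load(text))
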