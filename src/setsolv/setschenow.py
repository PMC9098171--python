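"""Setschenow-coefficient fitting and the separable ion/surfactant model.

A salt shifts the CMC of a nonionic surfactant log-linearly,

    ln(CMC / CMC0) = -k_s * C_salt,

with k_s the salt-specific Setschenow coefficient (positive = salting out).
Simulated and experimental k_s are linked to the DPD ion-tail repulsion
amplitudes through the separable model

    k_s = A * (1/a+ + 1/a-) + B,

where A (M^-1 kBT) and B (M^-1) characterize the surfactant and a+, a- are
the cation-tail and anion-tail repulsion amplitudes in kBT.  Because the two
ionic terms enter additively, a salt is the sum of the individual effects of
its ions, and parameters fitted on some surfactant/salt pairs transfer to
unseen combinations.

Fitting proceeds in the two stages used to build the parameter tables:
per-surfactant (A, B) by linear least squares given ion amplitudes, and ion
amplitudes by bounded nonlinear least squares given (A, B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .forcefield import ION_SCREEN_RANGE

__all__ = [
    "CMCSeries",
    "SetschenowFit",
    "Eq6Model",
    "fit_ks",
    "predict_ks",
    "fit_surfactant_ab",
    "fit_ion_amplitudes",
    "IonFitResult",
    "r_squared",
    "load_experimental_ks",
    "load_surfactant_params",
    "load_ion_params",
]


@dataclass(frozen=True)
class CMCSeries:
    """CMC versus salt concentration for one surfactant/salt combination."""

    surfactant: str
    concentrations: tuple[float, ...]  # mol/L
    cmcs: tuple[float, ...]  # mol/L
    cmc0: float | None = None  # zero-salt CMC; taken from the C=0 point if absent

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.cmcs):
            raise ValueError("concentration and CMC lists differ in length")
        if any(c < 0 for c in self.concentrations):
            raise ValueError("salt concentrations must be non-negative")
        if any(c <= 0 for c in self.cmcs) or (self.cmc0 is not None and self.cmc0 <= 0):
            raise ValueError("all CMC values must be positive")

    def reference_cmc(self) -> float:
        if self.cmc0 is not None:
            return self.cmc0
        for c, cmc in zip(self.concentrations, self.cmcs):
            if c == 0.0:
                return cmc
        raise ValueError("series has neither a C_salt=0 point nor an explicit CMC0")


@dataclass(frozen=True)
class SetschenowFit:
    """OLS fit of ln(CMC/CMC0) against C_salt; k_s = -slope."""

    ks: float
    intercept: float
    stderr: float
    n: int


def fit_ks(series: CMCSeries) -> SetschenowFit:
    """Setschenow coefficient of one CMC-salt series by ordinary least squares."""
    c = np.asarray(series.concentrations, dtype=float)
    if len(np.unique(c)) < 2:
        raise ValueError("need at least two distinct salt concentrations")
    y = np.log(np.asarray(series.cmcs, dtype=float) / series.reference_cmc())
    X = np.column_stack([c, np.ones_like(c)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    slope, intercept = coef
    resid = y - X @ coef
    dof = len(c) - 2
    if dof > 0:
        s2 = float(resid @ resid) / dof
        sxx = float(((c - c.mean()) ** 2).sum())
        stderr = float(np.sqrt(s2 / sxx)) if sxx > 0 else float("nan")
    else:
        stderr = 0.0
    return SetschenowFit(ks=-float(slope), intercept=float(intercept),
                         stderr=stderr, n=len(c))


@dataclass
class Eq6Model:
    """Separable model parameters: per-surfactant (A, B), per-ion amplitudes."""

    surfactants: dict[str, tuple[float, float]]  # name -> (A, B)
    ions: dict[str, float]  # name -> tail repulsion amplitude, kBT

    def __post_init__(self) -> None:
        for ion, amp in self.ions.items():
            if amp <= 0:
                raise ValueError(f"amplitude for {ion!r} must be positive")


def predict_ks(model: Eq6Model, surfactant: str, cation: str, anion: str) -> float:
    """k_s (M^-1) for a surfactant/salt combination from the separable model."""
    try:
        a_coef, b_coef = model.surfactants[surfactant]
    except KeyError:
        raise KeyError(f"no (A, B) parameters for surfactant {surfactant!r}") from None
    amps = []
    for ion in (cation, anion):
        try:
            amps.append(model.ions[ion])
        except KeyError:
            raise KeyError(f"no tail amplitude for ion {ion!r}") from None
    return a_coef * (1.0 / amps[0] + 1.0 / amps[1]) + b_coef


def fit_surfactant_ab(
    ks_table: pd.DataFrame, ion_amplitudes: dict[str, float]
) -> tuple[float, float, float]:
    """(A, B) for one surfactant from experimental k_s at known ion amplitudes.

    ``ks_table`` needs columns cation, anion, ks.  Linear least squares in the
    regressor x = 1/a+ + 1/a-; returns (A, B, sum of squared residuals).
    """
    if len(ks_table) < 2:
        raise ValueError("need at least two salts to determine A and B")
    x = np.array(
        [
            1.0 / ion_amplitudes[row.cation] + 1.0 / ion_amplitudes[row.anion]
            for row in ks_table.itertuples()
        ]
    )
    if np.ptp(x) < 1e-12:
        raise ValueError("design is rank-deficient: all salts share the same 1/a+ + 1/a-")
    y = ks_table["ks"].to_numpy(dtype=float)
    X = np.column_stack([x, np.ones_like(x)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


@dataclass
class IonFitResult:
    amplitudes: dict[str, float]
    residuals: pd.DataFrame
    ss_res: float
    weakly_identified: set[str] = field(default_factory=set)


def fit_ion_amplitudes(
    ks_table: pd.DataFrame,
    surfactant_params: dict[str, tuple[float, float]],
    bounds: tuple[float, float] = ION_SCREEN_RANGE,
    fixed: dict[str, float] | None = None,
    x0: float = 70.0,
) -> IonFitResult:
    """Ion-tail amplitudes from experimental k_s across surfactants.

    Joint bounded nonlinear least squares over all (surfactant, salt) rows
    with the surfactant constants held fixed.  Per-ion bounds can be pinned by
    passing equal lower/upper values through ``fixed``.  Ions supported by a
    single measurement are reported as weakly identified.
    """
    fixed = fixed or {}
    rows = ks_table.reset_index(drop=True)
    for col in ("surfactant", "cation", "anion", "ks"):
        if col not in rows.columns:
            raise ValueError(f"ks table is missing column {col!r}")
    missing = set(rows["surfactant"]) - set(surfactant_params)
    if missing:
        raise KeyError(f"no (A, B) parameters for surfactant(s) {sorted(missing)}")
    free_ions = sorted(
        (set(rows["cation"]) | set(rows["anion"])) - set(fixed)
    )
    if not free_ions:
        raise ValueError("no free ions to fit")
    idx = {ion: i for i, ion in enumerate(free_ions)}
    a_arr = np.array([surfactant_params[s][0] for s in rows["surfactant"]])
    b_arr = np.array([surfactant_params[s][1] for s in rows["surfactant"]])
    y = rows["ks"].to_numpy(dtype=float)

    def amp_of(ion: str, x: np.ndarray) -> np.ndarray | float:
        return fixed[ion] if ion in fixed else x[idx[ion]]

    def residual(x: np.ndarray) -> np.ndarray:
        inv = np.array(
            [
                1.0 / amp_of(c, x) + 1.0 / amp_of(a, x)
                for c, a in zip(rows["cation"], rows["anion"])
            ]
        )
        return a_arr * inv + b_arr - y

    lo, hi = bounds
    start = np.full(len(free_ions), float(np.clip(x0, lo, hi)))
    sol = least_squares(
        residual, start, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12
    )
    amplitudes = {ion: float(sol.x[idx[ion]]) for ion in free_ions}
    amplitudes.update(fixed)
    counts = pd.concat([rows["cation"], rows["anion"]]).value_counts()
    weak = {ion for ion in free_ions if counts.get(ion, 0) < 2}
    resid = residual(sol.x)
    table = rows[["surfactant", "cation", "anion", "ks"]].copy()
    table["ks_calc"] = y + resid
    table["residual"] = resid
    if weak:
        warnings.warn(
            f"ion(s) {sorted(weak)} constrained by a single measurement; "
            "amplitudes are weakly identified"
        )
    return IonFitResult(
        amplitudes=amplitudes,
        residuals=table,
        ss_res=float(resid @ resid),
        weakly_identified=weak,
    )


def r_squared(pairs) -> float:
    """Coefficient of determination of calculated against experimental k_s."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need at least two (experimental, calculated) pairs")
    exp, calc = arr[:, 0], arr[:, 1]
    ss_tot = float(((exp - exp.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("experimental values have zero variance")
    ss_res = float(((exp - calc) ** 2).sum())
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Packaged reference tables


def _data_path(name: str):
    return resources.files("setsolv.data").joinpath(name)


def load_experimental_ks(
    path: str | Path | None = None, monovalent_only: bool = False
) -> pd.DataFrame:
    """Experimental Setschenow coefficients (columns surfactant, cation,
    anion, ks, source_flag).  Fluoride rows are flagged ``excluded`` and
    divalent salts ``divalent``."""
    with resources.as_file(_data_path("experimental_ks.csv")) as p:
        df = pd.read_csv(path if path is not None else p)
    if monovalent_only:
        df = df[df["source_flag"] == "monovalent"].reset_index(drop=True)
    return df


def load_surfactant_params(path: str | Path | None = None) -> dict[str, tuple[float, float]]:
    """Per-surfactant (A, B) constants of the separable model."""
    with resources.as_file(_data_path("surfactant_params.csv")) as p:
        df = pd.read_csv(path if path is not None else p)
    return {r.surfactant: (float(r.A), float(r.B)) for r in df.itertuples()}


def load_ion_params(path: str | Path | None = None) -> dict[str, float]:
    """Per-ion tail repulsion amplitudes (kBT)."""
    with resources.as_file(_data_path("ion_params.csv")) as p:
        df = pd.read_csv(path if path is not None else p)
    return {r.ion: float(r.amplitude) for r in df.itertuples()}


def default_model() -> Eq6Model:
    """The packaged parameter tables as a ready-to-use separable model."""
    return Eq6Model(load_surfactant_params(), load_ion_params())
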