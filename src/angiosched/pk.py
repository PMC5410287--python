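"""One-compartment pharmacokinetics with first-order absorption.

Plasma concentrations of the two drugs act as forcing functions on the
tumor--vasculature dynamics: ``C(t)`` for the cytotoxic (paclitaxel) and
``A(t)`` for the antiangiogenic (bevacizumab).  Each intraperitoneal dose
contributes the classic Bateman profile

    c(t) = dose * scale * ka/(ka - ke) * (exp(-ke*dt) - exp(-ka*dt)),

with ``dt`` the time since that dose, and multi-dose schedules superpose
linearly.  All rates are in 1/day.

The amplitude of the profile is not separately identifiable from the
potency coefficients it multiplies in the pharmacodynamic model, so the
default ``scale`` equals ``ke``: a unit dose then has unit area under the
curve, and the potency parameters absorb any residual constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CYTOTOXIC",
    "ANTIANGIOGENIC",
    "DoseEvent",
    "PKParams",
    "ConcentrationSeries",
    "concentration_at",
    "concentration_series",
]

#: Drug-class identifiers used throughout the package.
CYTOTOXIC = "cytotoxic"
ANTIANGIOGENIC = "antiangiogenic"

_DRUG_CLASSES = (CYTOTOXIC, ANTIANGIOGENIC)


@dataclass(frozen=True)
class DoseEvent:
    """A single timed drug administration.

    Parameters
    ----------
    drug
        Drug class, ``"cytotoxic"`` or ``"antiangiogenic"``.
    time
        Administration day (days since graft), >= 0.
    dose
        Dose in mg/kg, >= 0.
    """

    drug: str
    time: float
    dose: float

    def __post_init__(self) -> None:
        if self.drug not in _DRUG_CLASSES:
            raise ValueError(
                f"unknown drug class {self.drug!r}; expected one of {_DRUG_CLASSES}"
            )
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")


@dataclass(frozen=True)
class PKParams:
    """Kinetic constants of the absorption/elimination profile.

    ``ka`` and ``ke`` are first-order rates in 1/day; ``scale`` converts a
    unit dose (mg/kg) into concentration units.  The closed form degenerates
    at ``ka == ke`` (flip-flop kinetics), which is rejected.
    """

    ka: float
    ke: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.ka > 0 and self.ke > 0):
            raise ValueError("absorption and elimination rates must be > 0")
        if self.ka == self.ke:
            raise ValueError(
                "ka == ke degenerates the two-exponential profile; "
                "perturb one of the rates"
            )
        if not self.scale > 0:
            raise ValueError("concentration scale must be > 0")

    @classmethod
    def from_half_lives(
        cls, t_half_abs: float, t_half_elim: float, scale: float | None = None
    ) -> "PKParams":
        """Build from absorption/elimination half-lives in days.

        When ``scale`` is omitted it is set to ``ke`` so that a unit dose
        has unit area under the concentration curve.
        """
        ka = np.log(2.0) / t_half_abs
        ke = np.log(2.0) / t_half_elim
        return cls(ka=ka, ke=ke, scale=ke if scale is None else scale)


@dataclass(frozen=True)
class ConcentrationSeries:
    """A concentration time course on a fixed grid (days, per-dose units)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have matching shapes")


def _single_dose_profile(
    params: PKParams, dose: float, dt: np.ndarray | float
) -> np.ndarray | float:
    """Bateman profile of one dose at elapsed time ``dt`` (0 before dosing)."""
    dt = np.asarray(dt, dtype=float)
    amp = dose * params.scale * params.ka / (params.ka - params.ke)
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        prof = amp * (np.exp(-params.ke * dt) - np.exp(-params.ka * dt))
    return np.where(dt >= 0.0, prof, 0.0)


def concentration_at(
    params: PKParams, doses: Iterable[DoseEvent], t: float
) -> float:
    """Plasma concentration at time ``t`` under a multi-dose schedule.

    Doses administered after ``t`` contribute nothing; earlier doses
    superpose linearly.
    """
    total = 0.0
    for dose in doses:
        if dose.time <= t:
            total += float(_single_dose_profile(params, dose.dose, t - dose.time))
    return total


def concentration_series(
    params: PKParams, doses: Sequence[DoseEvent], grid: np.ndarray
) -> ConcentrationSeries:
    """Vectorized concentration profile on a strictly increasing time grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("time grid must not be empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("time grid must be strictly increasing")
    values = np.zeros_like(grid)
    for dose in doses:
        values += _single_dose_profile(params, dose.dose, grid - dose.time)
    return ConcentrationSeries(times=grid, values=values)
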