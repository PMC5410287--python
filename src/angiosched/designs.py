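"""Treatment-arm templates for the two mouse experiments.

Both experiments graft luciferase-tagged MDA-MB-231 cells, start imaging at
day 8 and give three cycles of bevacizumab (antiangiogenic) and/or
paclitaxel (cytotoxic) by intraperitoneal injection:

* Experiment 1 — six arms, bevacizumab 10 mg/kg + paclitaxel 20 mg/kg,
  cycles on days 5/12/19, a 3-day lag in the sequential arms, followed to
  day 78.
* Experiment 2 — three arms (Control, concomitant BEVA-TXL, sequential
  BEVA/TXL), both drugs 20 mg/kg, cycles on days 11/21/31, 3-day lag,
  followed to day 52.

``ExperimentDesign`` also serves the gap scan: it knows the bevacizumab
cycle days and can place the paclitaxel doses any number of days later.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pk import ANTIANGIOGENIC, CYTOTOXIC, DoseEvent
from .dynamics import GroupSpec

__all__ = ["ExperimentDesign", "experiment_1", "experiment_2"]


def _cycle_doses(drug: str, days: tuple[float, ...], dose: float) -> tuple[DoseEvent, ...]:
    return tuple(DoseEvent(drug, day, dose) for day in days)


@dataclass(frozen=True)
class ExperimentDesign:
    """Dosing backbone of one experiment.

    ``beva_days`` are the cycle anchor days; sequential arms place each
    paclitaxel dose ``sequential_gap`` days after its cycle's bevacizumab.
    """

    name: str
    beva_days: tuple[float, ...]
    beva_dose: float
    txl_dose: float
    sequential_gap: float = 3.0
    horizon: float = 52.0
    t_I: float = 8.0
    obs_times: tuple[float, ...] = field(default_factory=tuple)

    def txl_days(self, gap: float) -> tuple[float, ...]:
        return tuple(day + gap for day in self.beva_days)

    def control(self) -> GroupSpec:
        return GroupSpec("Control", ())

    def beva_only(self) -> GroupSpec:
        return GroupSpec(
            "BEVA", _cycle_doses(ANTIANGIOGENIC, self.beva_days, self.beva_dose)
        )

    def txl_only(self) -> GroupSpec:
        return GroupSpec(
            "TXL", _cycle_doses(CYTOTOXIC, self.beva_days, self.txl_dose)
        )

    def concomitant(self) -> GroupSpec:
        """Both drugs on the cycle days (BEVA-TXL)."""
        return GroupSpec(
            "BEVA-TXL",
            _cycle_doses(ANTIANGIOGENIC, self.beva_days, self.beva_dose)
            + _cycle_doses(CYTOTOXIC, self.beva_days, self.txl_dose),
        )

    def sequential(self, gap: float | None = None) -> GroupSpec:
        """Bevacizumab first, paclitaxel ``gap`` days later (BEVA/TXL)."""
        gap = self.sequential_gap if gap is None else gap
        return GroupSpec(
            "BEVA/TXL",
            _cycle_doses(ANTIANGIOGENIC, self.beva_days, self.beva_dose)
            + _cycle_doses(CYTOTOXIC, self.txl_days(gap), self.txl_dose),
        )

    def reversed_sequential(self, gap: float | None = None) -> GroupSpec:
        """Paclitaxel first, bevacizumab ``gap`` days later (TXL/BEVA)."""
        gap = self.sequential_gap if gap is None else gap
        return GroupSpec(
            "TXL/BEVA",
            _cycle_doses(CYTOTOXIC, self.beva_days, self.txl_dose)
            + _cycle_doses(ANTIANGIOGENIC, self.txl_days(gap), self.beva_dose),
        )

    def groups(self) -> tuple[GroupSpec, ...]:
        """All arms of the experiment, Control first."""
        if self.name == "experiment_1":
            return (
                self.control(),
                self.beva_only(),
                self.txl_only(),
                self.concomitant(),
                self.sequential(),
                self.reversed_sequential(),
            )
        return (self.control(), self.concomitant(), self.sequential())

    def group(self, label: str) -> GroupSpec:
        for g in self.groups():
            if g.label == label:
                return g
        raise KeyError(f"no arm labelled {label!r} in {self.name}")


def _twice_weekly(start: float, end: float) -> tuple[float, ...]:
    """Imaging days alternating 3- and 4-day intervals, endpoint included."""
    times = [start]
    step = 3.0
    while times[-1] + step <= end:
        times.append(times[-1] + step)
        step = 7.0 - step
    if times[-1] < end:
        times.append(end)
    return tuple(times)


def experiment_1() -> ExperimentDesign:
    """Six-arm design: 10 mg/kg bevacizumab, cycles D5/D12/D19, to day 78."""
    return ExperimentDesign(
        name="experiment_1",
        beva_days=(5.0, 12.0, 19.0),
        beva_dose=10.0,
        txl_dose=20.0,
        sequential_gap=3.0,
        horizon=78.0,
        t_I=8.0,
        obs_times=_twice_weekly(8.0, 78.0),
    )


def experiment_2() -> ExperimentDesign:
    """Three-arm design: 20 mg/kg both drugs, cycles D11/D21/D31, to day 52."""
    return ExperimentDesign(
        name="experiment_2",
        beva_days=(11.0, 21.0, 31.0),
        beva_dose=20.0,
        txl_dose=20.0,
        sequential_gap=3.0,
        horizon=52.0,
        t_I=8.0,
        obs_times=_twice_weekly(8.0, 52.0),
    )
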