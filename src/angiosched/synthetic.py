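"""Study-shaped synthetic data for end-to-end testing of the pipeline.

Generates the two kinds of input the analysis consumes, without any
download:

* grouped bioluminescence fold-increase kinetics — each arm's mean curve is
  the model burden ``N(t)`` corrupted by per-animal multiplicative
  lognormal noise (bioluminescence error is multiplicative; the large
  s.e.m. typical of such studies motivates the default CV of 0.3);
* per-animal metastasis onset times — drawn from an inhomogeneous
  exponential clock with hazard proportional to the simulated burden,
  ``lambda(t) = beta * N(t)``.  This hazard model is a deliberate,
  documented stand-in: the growth models make no claim about metastasis,
  and the clock exists purely to exercise the incidence statistics.

All generators are pure functions of (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .calibration import ObservedSeries
from .defaults import default_model_params, default_pk
from .designs import ExperimentDesign, experiment_1, experiment_2
from .dynamics import (
    ModelParams,
    SimOutput,
    SimulationError,
    VASCULAR_KILL_COMBINED,
    simulate,
)
from .metastasis import IncidenceData
from .pk import ANTIANGIOGENIC, CYTOTOXIC, PKParams

__all__ = ["SynthDesign", "generate_growth_data", "generate_metastasis_times"]


@dataclass(frozen=True)
class SynthDesign:
    """A fully specified synthetic experiment.

    ``experiment`` selects the dosing template (1: six arms, 8
    animals/group; 2: three arms, 12 animals/group).  ``true_params`` is
    the generating parameter vector; observation times default to the
    template's imaging days.
    """

    experiment: int = 2
    noise_cv: float = 0.3
    n_per_group: int | None = None
    seed: int = 0
    true_params: ModelParams | None = None
    obs_times: tuple[float, ...] = ()
    pk_cyto: PKParams | None = None
    pk_anti: PKParams | None = None
    vascular_kill: str = VASCULAR_KILL_COMBINED

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_per_group is not None and self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")

    @property
    def template(self) -> ExperimentDesign:
        return experiment_1() if self.experiment == 1 else experiment_2()

    @property
    def animals(self) -> int:
        if self.n_per_group is not None:
            return self.n_per_group
        return 8 if self.experiment == 1 else 12

    def resolve(self, model_id: int) -> tuple[ModelParams, PKParams, PKParams, np.ndarray]:
        params = self.true_params or default_model_params(model_id)
        pk = default_pk()
        pk_c = self.pk_cyto or pk[CYTOTOXIC]
        pk_a = self.pk_anti or pk[ANTIANGIOGENIC]
        times = np.asarray(self.obs_times or self.template.obs_times, dtype=float)
        if times[0] < params.t_I:
            raise ValueError("observation times must start at or after t_I")
        return params, pk_c, pk_a, times


def _lognormal_noise(
    rng: np.random.Generator, cv: float, shape: tuple[int, ...]
) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


def generate_growth_data(
    design: SynthDesign, model_id: int = 2
) -> list[ObservedSeries]:
    """Per-arm mean fold-increase series with s.e.m. over simulated animals.

    The noise-free trajectory is simulated once per arm at the true
    parameters (any failure there aborts before sampling); each animal's
    series is that trajectory times i.i.d. lognormal noise.
    """
    params, pk_c, pk_a, times = design.resolve(model_id)
    template = design.template
    rng = np.random.default_rng(design.seed)
    n = design.animals

    sims: list[tuple[str, np.ndarray]] = []
    for group in template.groups():
        sim = simulate(
            model_id,
            params,
            group,
            pk_c,
            pk_a,
            t_span=(params.t_I, float(times[-1])),
            output_grid=times,
            vascular_kill=design.vascular_kill,
        )
        sims.append((group.label, sim.N))

    series = []
    for label, N in sims:
        animals = N[None, :] * _lognormal_noise(rng, design.noise_cv, (n, times.size))
        mean = animals.mean(axis=0)
        if design.noise_cv == 0 or n == 1:
            mean, sem = N.copy(), np.zeros_like(N)
        else:
            sem = animals.std(axis=0, ddof=1) / np.sqrt(n)
        series.append(ObservedSeries(group=label, times=times, y=mean, sem=sem, n=n))
    return series


def generate_metastasis_times(
    sim: SimOutput,
    beta: float,
    study_end: float,
    n_animals: int,
    seed: int,
    site: str = "any",
) -> IncidenceData:
    """Metastasis onsets from the burden-proportional hazard clock.

    Onset times come from time-rescaling: with cumulative hazard
    ``Lambda(t) = beta * int_{t_I}^t N(s) ds``, each animal's onset solves
    ``Lambda(t) = E`` for an independent Exp(1) draw ``E``; animals whose
    ``E`` exceeds ``Lambda(study_end)`` are censored (NaN).  Before the
    first observation day the hazard is zero.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if sim.times[-1] < study_end - 1e-9:
        raise SimulationError(
            f"trajectory ends at day {sim.times[-1]}, before study end {study_end}"
        )
    rng = np.random.default_rng(seed)
    mask = sim.times <= study_end + 1e-9
    t = sim.times[mask]
    cum_hazard = beta * cumulative_trapezoid(sim.N[mask], t, initial=0.0)
    draws = rng.exponential(1.0, size=n_animals)
    onset = np.where(
        draws <= cum_hazard[-1],
        np.interp(draws, cum_hazard, t),
        np.nan,
    )
    onset = np.where(onset > study_end, study_end, onset)
    return IncidenceData(sim.group, site, onset, duration=study_end)
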