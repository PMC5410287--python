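"""Least-squares calibration of the tumor--vasculature models.

Grouped mean fold-increase kinetics from all arms are pooled into one
unweighted sum-of-squares objective,

    J(theta) = sum_g sum_i (y_gi - N(t_i; theta, g))^2,

with a single shared parameter vector: only the drug scheduling differs
between arms.  Minimization follows the two-step procedure used in this
kind of PK/PD work — a coarse exploration of parameter space (here an
optional deterministic log-spaced multi-start) followed by Nelder--Mead
refinement.  Optimization runs in log-parameter space, which enforces
positivity and makes simplex steps scale-free.

Asymptotic standard errors come from the finite-difference sensitivity
matrix ``S`` of model predictions with respect to the free parameters:
``sigma^2 = J_min / (n_obs - n_params)`` and ``cov = sigma^2 (S'S)^-1``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .dynamics import (
    GroupSpec,
    ModelParams,
    SimulationError,
    VASCULAR_KILL_COMBINED,
    simulate,
)
from .pk import PKParams

__all__ = [
    "ObservedSeries",
    "FitResult",
    "CalibrationProblem",
    "objective",
    "prefit_control",
    "fit",
    "standard_errors",
]

logger = logging.getLogger(__name__)

#: Penalty returned when a simulation fails inside the optimizer.
_PENALTY = 1e12


@dataclass(frozen=True)
class ObservedSeries:
    """Grouped mean fold-increase kinetics for one treatment arm.

    ``y`` is the mean over animals of bioluminescence fold increase
    relative to the first imaging day; ``sem`` and ``n`` are carried for
    plotting/synthesis and optional weighting, not for the default fit.
    """

    group: str
    times: np.ndarray
    y: np.ndarray
    sem: np.ndarray | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.sem is not None:
            object.__setattr__(self, "sem", np.asarray(self.sem, dtype=float))
        if self.times.ndim != 1 or self.times.shape != self.y.shape:
            raise ValueError("times and y must be 1-D arrays of equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any(self.y <= 0):
            raise ValueError("fold-increase observations must be > 0")


@dataclass
class FitResult:
    """Outcome of a calibration run."""

    theta_hat: dict[str, float]
    free: tuple[str, ...]
    J_min: float
    converged: bool
    n_obs: int
    n_params: int
    se: dict[str, float] | None = None
    n_fev: int = 0
    message: str = ""

    def params(self, base: ModelParams) -> ModelParams:
        """Base parameters with the fitted values substituted in."""
        return base.with_updates(**self.theta_hat)


@dataclass
class CalibrationProblem:
    """Everything the objective needs besides the free-parameter values.

    ``groups`` maps each observed series' label to its dose schedule;
    ``base_params`` supplies every pinned parameter (tau stays pinned at 0
    unless explicitly freed).  ``weighted`` switches on 1/sem^2 weighting
    (off by default: the reference procedure is unweighted).
    """

    datasets: Sequence[ObservedSeries]
    model_id: int
    groups: Mapping[str, GroupSpec]
    base_params: ModelParams
    pk_cyto: PKParams
    pk_anti: PKParams
    free: tuple[str, ...]
    rtol: float = 1e-9
    vascular_kill: str = VASCULAR_KILL_COMBINED
    weighted: bool = False
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for series in self.datasets:
            if series.group not in self.groups:
                raise KeyError(
                    f"dataset group {series.group!r} has no schedule in `groups`"
                )
        self.free = tuple(self.free)

    @property
    def n_obs(self) -> int:
        return int(sum(s.times.size for s in self.datasets))

    def params_at(self, theta: Mapping[str, float]) -> ModelParams:
        unknown = set(theta) - set(self.free)
        if unknown:
            raise KeyError(f"theta contains non-free parameters: {sorted(unknown)}")
        return self.base_params.with_updates(**dict(theta))

    def predict(self, theta: Mapping[str, float]) -> np.ndarray:
        """Model burden N at every observation time, concatenated over arms."""
        params = self.params_at(theta)
        horizon = max(s.times[-1] for s in self.datasets)
        preds = []
        for series in self.datasets:
            sim = simulate(
                self.model_id,
                params,
                self.groups[series.group],
                self.pk_cyto,
                self.pk_anti,
                t_span=(params.t_I, horizon),
                output_grid=series.times,
                rtol=self.rtol,
                vascular_kill=self.vascular_kill,
            )
            preds.append(sim.N)
        return np.concatenate(preds)

    def observations(self) -> np.ndarray:
        return np.concatenate([s.y for s in self.datasets])

    def _weights(self) -> np.ndarray:
        if not self.weighted:
            return np.ones(self.n_obs)
        sems = []
        for s in self.datasets:
            if s.sem is None:
                raise ValueError(f"weighted fit needs sem for group {s.group!r}")
            sems.append(np.where(s.sem > 0, s.sem, np.inf))
        w = 1.0 / np.concatenate(sems) ** 2
        return np.where(np.isfinite(w), w, 0.0)


def objective(theta: Mapping[str, float], problem: CalibrationProblem) -> float:
    """Pooled (optionally weighted) sum of squared residuals at ``theta``.

    A failed simulation yields a large finite penalty — inflated by the
    distance of ``theta`` from its bounds — so the simplex can recover.
    """
    try:
        params = problem.params_at(theta)
    except ValueError as exc:  # invalid parameter combination
        logger.debug("invalid theta %s: %s", dict(theta), exc)
        return _PENALTY + _bound_distance(theta, problem)
    try:
        preds = problem.predict(theta)
    except (SimulationError, ValueError) as exc:
        logger.debug("simulation failed at theta %s: %s", dict(theta), exc)
        return _PENALTY + _bound_distance(theta, problem)
    resid = problem.observations() - preds
    with np.errstate(over="ignore"):
        J = float(np.sum(problem._weights() * resid**2))
    if not np.isfinite(J):
        logger.debug("non-finite objective at theta %s", dict(theta))
        return _PENALTY + _bound_distance(theta, problem)
    return J


def _bound_distance(theta: Mapping[str, float], problem: CalibrationProblem) -> float:
    dist = 0.0
    for name, value in theta.items():
        lo, hi = problem.bounds.get(name, (0.0, np.inf))
        if value < lo:
            dist += lo - value
        elif value > hi:
            dist += value - hi
    return dist


def _default_bounds(free: Sequence[str]) -> dict[str, tuple[float, float]]:
    bounds = {name: (0.0, np.inf) for name in free}
    if "qbar" in bounds:
        bounds["qbar"] = (1e-6, 1.0)
    return bounds


def _to_log(theta: Mapping[str, float], free: Sequence[str]) -> np.ndarray:
    return np.array([math.log(max(theta[name], 1e-300)) for name in free])


def _from_log(x: np.ndarray, free: Sequence[str]) -> dict[str, float]:
    return {name: float(math.exp(v)) for name, v in zip(free, x)}


def fit(
    problem: CalibrationProblem,
    init: Mapping[str, float],
    multistart: bool = False,
    maxiter: int | None = None,
    fatol: float = 1e-10,
    xatol: float = 1e-6,
    max_restarts: int = 2,
) -> FitResult:
    """Nelder--Mead minimization of the pooled objective.

    ``init`` must supply a starting value for every free parameter.  With
    ``multistart`` the simplex is launched from a deterministic log-spaced
    grid (3 points per parameter, factors 1/4, 1, 4 around ``init``, capped
    at 81 starts) and the best run wins — an automated stand-in for manual
    exploration of parameter space.  Non-convergence after ``max_restarts``
    re-launches from the incumbent is reported, never silenced.
    """
    free = problem.free
    missing = set(free) - set(init)
    if missing:
        raise KeyError(f"init lacks free parameters: {sorted(missing)}")
    if not problem.bounds:
        problem.bounds = _default_bounds(free)
    n_params = len(free)
    if problem.n_obs <= n_params:
        raise ValueError(
            f"need more observations ({problem.n_obs}) than free parameters "
            f"({n_params})"
        )

    def f(x: np.ndarray) -> float:
        return objective(_from_log(x, free), problem)

    x0 = _to_log({k: init[k] for k in free}, free)
    starts = [x0]
    if multistart:
        offsets = (math.log(0.25), 0.0, math.log(4.0))
        grid = itertools.product(offsets, repeat=n_params)
        starts = [x0 + np.array(off) for off in itertools.islice(grid, 81)]

    options = {"fatol": fatol, "xatol": xatol}
    if maxiter is not None:
        options["maxiter"] = maxiter
    best = None
    n_fev = 0
    for x_start in starts:
        res = optimize.minimize(f, x_start, method="Nelder-Mead", options=options)
        n_fev += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success)
    for _ in range(max_restarts):
        if converged:
            break
        res = optimize.minimize(f, best.x, method="Nelder-Mead", options=options)
        n_fev += res.nfev
        if res.fun <= best.fun:
            best = res
        converged = bool(res.success)
    if not converged:
        logger.warning("fit did not converge: %s", best.message)

    theta_hat = _from_log(best.x, free)
    return FitResult(
        theta_hat=theta_hat,
        free=free,
        J_min=float(best.fun),
        converged=converged,
        n_obs=problem.n_obs,
        n_params=n_params,
        n_fev=n_fev,
        message=str(best.message),
    )


def prefit_control(
    control_series: ObservedSeries,
    model_id: int,
    base_params: ModelParams,
    pk_cyto: PKParams,
    pk_anti: PKParams,
    init: Mapping[str, float] | None = None,
    rtol: float = 1e-9,
    **fit_kwargs,
) -> dict[str, float]:
    """Growth parameters (a, b, d, K0) from the untreated arm alone.

    Seeds (and optionally pins) the joint fit; for model 2 the fitted
    ``K0`` sets the initial stable pool (``S0`` defaults to ``K0``).
    """
    if control_series.times.size < 4:
        raise ValueError("control prefit needs at least 4 time points")
    free = ("a", "b", "d", "K0")
    problem = CalibrationProblem(
        datasets=[control_series],
        model_id=model_id,
        groups={control_series.group: GroupSpec(control_series.group, ())},
        base_params=base_params,
        pk_cyto=pk_cyto,
        pk_anti=pk_anti,
        free=free,
        rtol=rtol,
    )
    if init is None:
        init = {"a": 0.1, "b": 1.0, "d": 0.01, "K0": 5.0}
    result = fit(problem, init, **fit_kwargs)
    return result.theta_hat


def standard_errors(
    fit_result: FitResult,
    problem: CalibrationProblem | None = None,
    predict_fn: Callable[[Mapping[str, float]], np.ndarray] | None = None,
    rel_step: float = 1e-4,
) -> dict[str, float]:
    """Asymptotic standard errors from finite-difference sensitivities.

    ``sigma^2 = J_min/(n_obs - n_params)``; the sensitivity matrix uses
    central differences with relative step ``rel_step`` on each free
    parameter.  ``predict_fn`` overrides the problem's predictor (useful
    for plugging in closed-form models).  A singular information matrix is
    reported with the names of the unidentifiable parameters.
    """
    if predict_fn is None:
        if problem is None:
            raise ValueError("either a problem or a predict_fn is required")
        predict_fn = problem.predict
    theta = dict(fit_result.theta_hat)
    free = fit_result.free
    dof = fit_result.n_obs - fit_result.n_params
    if dof <= 0:
        raise ValueError("standard errors need n_obs > n_params")
    sigma2 = fit_result.J_min / dof

    cols = []
    for name in free:
        h = rel_step * max(abs(theta[name]), 1e-12)
        up = dict(theta, **{name: theta[name] + h})
        dn = dict(theta, **{name: theta[name] - h})
        cols.append((predict_fn(up) - predict_fn(dn)) / (2.0 * h))
    S = np.column_stack(cols)
    info = S.T @ S
    cond = np.linalg.cond(info)
    if not np.isfinite(cond) or cond > 1e14:
        # name the flat directions via the smallest singular vectors
        _, svals, vt = np.linalg.svd(S, full_matrices=False)
        flat = [
            free[int(np.argmax(np.abs(vt[i])))]
            for i, s in enumerate(svals)
            if s < 1e-10 * max(svals.max(), 1.0)
        ]
        raise np.linalg.LinAlgError(
            "singular sensitivity matrix; unidentifiable parameter(s): "
            + ", ".join(sorted(set(flat)) or ["<unresolved>"])
        )
    cov = sigma2 * np.linalg.inv(info)
    se = {name: float(math.sqrt(max(cov[i, i], 0.0))) for i, name in enumerate(free)}
    fit_result.se = se
    return se
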