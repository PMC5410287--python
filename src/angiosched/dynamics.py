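"""Tumor--vasculature pharmacodynamic models.

Two nested ODE models describe the response of an orthotopic tumor to a
cytotoxic (concentration ``C(t)``) combined with an antiangiogenic
(concentration ``A(t)``).  Both start from Hahnfeldt-type Gompertz growth
with a dynamic carrying capacity and a three-stage transit chain
``Z1 -> Z2 -> Z3`` for drug-hit cells (delayed cell death); the observable
burden is ``N = V + Z1 + Z2 + Z3``, in fold-increase units of the initial
bioluminescence signal.

Model 1 (constant vasculature quality Q per arm):

    dV/dt  = a V ln(K/V) - e_txl K Q C V
    dK/dt  = b V - d V^(2/3) K - [vascular kill] K
    dZ1/dt = e_txl K Q C V - k Z1
    dZ2/dt = k Z1 - k Z2
    dZ3/dt = k Z2 - k Z3

Model 2 splits the capacity into unstable (immature, ``U``) and stable
(mature, ``S``) vessel pools; quality emerges as ``Q(t) = S/(S+U)``:

    dV/dt  = a V ln(S/V) - e_txl S Q C V
    dU/dt  = b V - d V^(2/3) U - chi U - [vascular kill] U
    dS/dt  = chi U - tau S

The vascular kill term has two selectable readings (see
``VASCULAR_KILL_COMBINED``): the default credits the cytotoxic with its own
anti-endothelial action (endothelial cells ~5x more sensitive than tumor
cells), ``(e_beva*A + 5*e_txl*C) * (delivery factor) * (target pool)``; the
alternative drives the term by the antiangiogenic concentration alone,
``(e_beva + 5*e_ct) * (delivery factor) * A * (target pool)``.  The delivery
factor is ``K*Q`` (model 1) or ``S*Q`` (model 2), mirroring the delivery
modulation of the tumor kill term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .pk import ANTIANGIOGENIC, CYTOTOXIC, ConcentrationSeries, DoseEvent, PKParams

__all__ = [
    "ModelParams",
    "GroupSpec",
    "SimOutput",
    "SimulationError",
    "VASCULAR_KILL_COMBINED",
    "VASCULAR_KILL_LITERAL",
    "rhs_model1",
    "rhs_model2",
    "simulate",
    "quality_trajectory",
    "delivery_fold_change",
]

#: Vascular kill variant where paclitaxel contributes its anti-endothelial
#: effect: (e_beva*A + 5*e_txl*C) * delivery * pool.  Package default.
VASCULAR_KILL_COMBINED = "combined"
#: Literal single-drug variant: (e_beva + 5*e_ct) * delivery * A * pool.
VASCULAR_KILL_LITERAL = "literal"

_TINY_V = 1e-12


class SimulationError(RuntimeError):
    """Raised when an ODE integration fails or leaves the model domain."""


@dataclass(frozen=True)
class ModelParams:
    """All pharmacodynamic parameters, rates in 1/day, states in fold units.

    Attributes
    ----------
    a : Gompertz proliferation rate.
    b : endogenous angiogenesis stimulation.
    d : endogenous angiogenesis inhibition (per day per fold^(2/3)).
    e_txl : cytotoxic potency of paclitaxel (per concentration per day).
    e_beva : antiangiogenic potency of bevacizumab.
    e_ct : antiangiogenic potency of the cytotoxic in the literal kill
        variant; defaults to ``e_txl`` when not set.
    k : transit rate through the dying-cell chain.
    chi : vessel stabilization (maturation) rate, model 2.
    tau : stable-vessel loss rate, model 2; fixed at 0 by default because
        calibrations persistently drive it below numerical noise.
    qbar : constant quality of the concomitant arm under model 1, in (0, 1].
    K0 : initial carrying capacity (model 1).
    U0, S0 : initial unstable/stable vessel pools (model 2); ``S0`` defaults
        to ``K0`` and ``U0`` to 0 so quality starts at its baseline of 1.
    t_I : first observation day; all initial conditions are anchored there.
    """

    a: float
    b: float
    d: float
    e_txl: float
    e_beva: float
    k: float = 1.0
    chi: float = 0.0
    tau: float = 0.0
    qbar: float = 1.0
    K0: float = 1.0
    U0: float = 0.0
    S0: float | None = None
    e_ct: float | None = None
    t_I: float = 8.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "d", "e_txl", "e_beva", "k", "chi", "tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")
        if not (0.0 < self.qbar <= 1.0):
            raise ValueError("qbar must lie in (0, 1]")
        if not self.K0 > 0:
            raise ValueError("K0 must be > 0")
        if self.U0 < 0:
            raise ValueError("U0 must be >= 0")
        if self.S0 is not None and not self.S0 > 0:
            raise ValueError("S0 must be > 0")

    @property
    def s0(self) -> float:
        return self.K0 if self.S0 is None else self.S0

    @property
    def ect(self) -> float:
        return self.e_txl if self.e_ct is None else self.e_ct

    def with_updates(self, **kwargs: float) -> "ModelParams":
        return replace(self, **kwargs)


#: Arm labels with a conventional quality assignment under model 1.
_CONCOMITANT_LABELS = {"BEVA-TXL"}


@dataclass(frozen=True)
class GroupSpec:
    """A treatment arm: label, dose schedule and model-1 quality policy.

    ``quality`` selects the constant Q used by model 1: a float pins it,
    ``"qbar"`` uses ``ModelParams.qbar``, ``"auto"`` (default) assigns
    ``qbar`` to the concomitant arm (label ``BEVA-TXL``) and 1 elsewhere.
    Model 2 ignores this field (quality is a state-derived quantity).
    """

    label: str
    schedule: tuple[DoseEvent, ...] = field(default_factory=tuple)
    quality: float | str = "auto"

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule", tuple(self.schedule))

    def constant_quality(self, params: ModelParams) -> float:
        if isinstance(self.quality, (int, float)):
            q = float(self.quality)
        elif self.quality == "qbar":
            q = params.qbar
        elif self.quality == "auto":
            q = params.qbar if self.label in _CONCOMITANT_LABELS else 1.0
        else:
            raise ValueError(f"unknown quality policy {self.quality!r}")
        if not (0.0 < q <= 1.0):
            raise ValueError(f"constant quality must lie in (0, 1], got {q}")
        return q

    def doses(self, drug: str) -> tuple[DoseEvent, ...]:
        return tuple(d for d in self.schedule if d.drug == drug)


@dataclass(frozen=True)
class SimOutput:
    """State trajectories on the output grid.

    ``K`` holds the carrying capacity for model 1; for model 2 it holds the
    total vasculature ``U + S`` while ``U`` and ``S`` carry the pools.
    """

    model_id: int
    group: str
    times: np.ndarray
    V: np.ndarray
    K: np.ndarray
    Z1: np.ndarray
    Z2: np.ndarray
    Z3: np.ndarray
    N: np.ndarray
    Q: np.ndarray
    U: np.ndarray | None = None
    S: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy trajectory table (one row per time point)."""
        return pd.DataFrame(
            {
                "group": self.group,
                "time_days": self.times,
                "V": self.V,
                "U_or_K": self.U if self.U is not None else self.K,
                "S": self.S if self.S is not None else np.nan,
                "Z1": self.Z1,
                "Z2": self.Z2,
                "Z3": self.Z3,
                "N": self.N,
                "Q": self.Q,
            }
        )

    def burden_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """Interpolate total burden N at arbitrary times within the grid."""
        return np.interp(t, self.times, self.N)


def _vascular_kill_rate(
    c: float,
    a_conc: float,
    delivery: float,
    params: ModelParams,
    variant: str,
) -> float:
    if variant == VASCULAR_KILL_COMBINED:
        return (params.e_beva * a_conc + 5.0 * params.e_txl * c) * delivery
    if variant == VASCULAR_KILL_LITERAL:
        return (params.e_beva + 5.0 * params.ect) * delivery * a_conc
    raise ValueError(f"unknown vascular kill variant {variant!r}")


def rhs_model1(
    state: Sequence[float],
    t: float,
    params: ModelParams,
    C: Callable[[float], float],
    A: Callable[[float], float],
    Q: float,
    vascular_kill: str = VASCULAR_KILL_COMBINED,
) -> np.ndarray:
    """Right-hand side of model 1 at time ``t`` (days)."""
    V, K, Z1, Z2, Z3 = state
    if V <= 0.0:
        raise SimulationError(f"tumor state V = {V} out of domain at t = {t}")
    c, a_conc = C(t), A(t)
    kill = params.e_txl * K * Q * c * V
    dV = params.a * V * math.log(K / V) - kill
    vkill = _vascular_kill_rate(c, a_conc, K * Q, params, vascular_kill)
    dK = params.b * V - params.d * V ** (2.0 / 3.0) * K - vkill * K
    dZ1 = kill - params.k * Z1
    dZ2 = params.k * (Z1 - Z2)
    dZ3 = params.k * (Z2 - Z3)
    return np.array([dV, dK, dZ1, dZ2, dZ3])


def rhs_model2(
    state: Sequence[float],
    t: float,
    params: ModelParams,
    C: Callable[[float], float],
    A: Callable[[float], float],
    vascular_kill: str = VASCULAR_KILL_COMBINED,
) -> np.ndarray:
    """Right-hand side of model 2 at time ``t`` (days)."""
    V, U, S, Z1, Z2, Z3 = state
    if V <= 0.0:
        raise SimulationError(f"tumor state V = {V} out of domain at t = {t}")
    if S + U <= 0.0:
        raise SimulationError(f"vasculature S + U = {S + U} vanished at t = {t}")
    Q = S / (S + U)
    c, a_conc = C(t), A(t)
    kill = params.e_txl * S * Q * c * V
    dV = params.a * V * math.log(S / V) - kill
    vkill = _vascular_kill_rate(c, a_conc, S * Q, params, vascular_kill)
    dU = params.b * V - params.d * V ** (2.0 / 3.0) * U - params.chi * U - vkill * U
    dS = params.chi * U - params.tau * S
    dZ1 = kill - params.k * Z1
    dZ2 = params.k * (Z1 - Z2)
    dZ3 = params.k * (Z2 - Z3)
    return np.array([dV, dU, dS, dZ1, dZ2, dZ3])


def _forcing(pk: PKParams, doses: tuple[DoseEvent, ...]) -> Callable[[float], float]:
    """Closed-form concentration as a scalar function of time."""
    if not doses:
        return lambda t: 0.0
    times = np.array([d.time for d in doses])
    amps = np.array(
        [d.dose * pk.scale * pk.ka / (pk.ka - pk.ke) for d in doses]
    )
    ka, ke = pk.ka, pk.ke

    def conc(t: float) -> float:
        total = 0.0
        for t0, amp in zip(times, amps):
            dt = t - t0
            if dt >= 0.0:
                total += amp * (math.exp(-ke * dt) - math.exp(-ka * dt))
        return total

    return conc


def _segment_boundaries(
    schedule: tuple[DoseEvent, ...], t0: float, t1: float
) -> np.ndarray:
    """Integration breakpoints: span endpoints plus interior dose times."""
    interior = sorted({d.time for d in schedule if t0 < d.time < t1})
    return np.array([t0, *interior, t1])


def simulate(
    model_id: int,
    params: ModelParams,
    group: GroupSpec,
    pk_cyto: PKParams,
    pk_anti: PKParams,
    t_span: tuple[float, float] | None = None,
    output_grid: np.ndarray | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    method: str = "LSODA",
    vascular_kill: str = VASCULAR_KILL_COMBINED,
) -> SimOutput:
    """Integrate model 1 or 2 for one treatment arm.

    The integration restarts at every dose time so the kink in the forcing
    derivative never straddles a solver step.  Initial conditions follow the
    model definition: ``V = 1`` and empty kill chain at ``t_I``, with
    ``K = K0`` (model 1) or ``U = U0, S = S0`` (model 2).

    Parameters
    ----------
    t_span
        Integration window in days; defaults to ``(t_I, last dose + 21)``.
    output_grid
        Times at which states are reported; defaults to 0.1-day spacing
        over ``t_span``.  Must lie within ``t_span`` and start at its left
        endpoint.
    rtol
        Relative solver tolerance; the stiff PK forcing makes tight
        tolerances necessary, hence the 1e-9 default.
    """
    if model_id not in (1, 2):
        raise ValueError(f"model_id must be 1 or 2, got {model_id}")
    if t_span is None:
        last = max((d.time for d in group.schedule), default=params.t_I)
        t_span = (params.t_I, last + 21.0)
    t0, t1 = map(float, t_span)
    if t1 <= t0:
        raise ValueError("t_span must be increasing")
    if output_grid is None:
        output_grid = np.linspace(t0, t1, max(2, int(round((t1 - t0) / 0.1)) + 1))
    grid = np.asarray(output_grid, dtype=float)
    if grid[0] < t0 - 1e-9 or grid[-1] > t1 + 1e-9:
        raise ValueError("output grid must lie within t_span")
    grid = np.clip(grid, t0, t1)  # absorb float-accumulation overshoot

    C = _forcing(pk_cyto, group.doses(CYTOTOXIC))
    A = _forcing(pk_anti, group.doses(ANTIANGIOGENIC))

    if model_id == 1:
        q_const = group.constant_quality(params)
        y0 = np.array([1.0, params.K0, 0.0, 0.0, 0.0])

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            return rhs_model1(y, t, params, C, A, q_const, vascular_kill)

    else:
        y0 = np.array([1.0, params.U0, params.s0, 0.0, 0.0, 0.0])

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            return rhs_model2(y, t, params, C, A, vascular_kill)

    bounds = _segment_boundaries(group.schedule, t0, t1)
    states = np.empty((y0.size, grid.size))
    filled = 0
    y = y0
    for seg_start, seg_end in zip(bounds[:-1], bounds[1:]):
        # grid points not yet reported that fall inside this segment;
        # always evaluate the segment endpoint to hand the state over
        pending = grid[filled:]
        in_seg = np.clip(pending[pending <= seg_end + 1e-12], seg_start, seg_end)
        n_in = in_seg.size
        appended = n_in == 0 or in_seg[-1] < seg_end
        t_eval = np.append(in_seg, seg_end) if appended else in_seg
        try:
            sol = solve_ivp(
                rhs,
                (seg_start, seg_end),
                y,
                method=method,
                t_eval=t_eval,
                rtol=rtol,
                atol=atol,
            )
        except SimulationError as exc:
            raise SimulationError(
                f"arm {group.label!r}, model {model_id}: {exc}"
            ) from exc
        if not sol.success:
            raise SimulationError(
                f"arm {group.label!r}, model {model_id}: solver failed in "
                f"[{seg_start}, {seg_end}] days: {sol.message}"
            )
        states[:, filled : filled + n_in] = sol.y[:, :n_in]
        filled += n_in
        y = sol.y[:, -1]
    if filled != grid.size:
        raise SimulationError(
            f"arm {group.label!r}: output grid only filled to {filled}/{grid.size}"
        )
    if not np.all(np.isfinite(states)):
        raise SimulationError(f"arm {group.label!r}: non-finite states in output")

    if model_id == 1:
        V, K, Z1, Z2, Z3 = states
        N = V + Z1 + Z2 + Z3
        Q = np.full_like(V, group.constant_quality(params))
        return SimOutput(1, group.label, grid, V, K, Z1, Z2, Z3, N, Q)
    V, U, S, Z1, Z2, Z3 = states
    N = V + Z1 + Z2 + Z3
    Q = S / (S + U)
    return SimOutput(2, group.label, grid, V, U + S, Z1, Z2, Z3, N, Q, U=U, S=S)


def quality_trajectory(sim: SimOutput) -> ConcentrationSeries:
    """Vasculature quality ``Q(t) = S/(S+U)`` along a model-2 trajectory."""
    if sim.model_id != 2 or sim.U is None or sim.S is None:
        raise ValueError(
            "quality is a state-derived quantity only under model 2; "
            "model 1 arms carry a constant Q (see SimOutput.Q)"
        )
    return ConcentrationSeries(times=sim.times, values=sim.S / (sim.S + sim.U))


def delivery_fold_change(q_reference: float, q_improved: float = 1.0) -> float:
    """Fold change in drug delivery implied by two constant qualities.

    Under model 1 the cytotoxic exposure scales linearly with Q, so an arm
    at quality ``q_improved`` receives ``q_improved / q_reference`` times
    the drug delivered at quality ``q_reference``.
    """
    if not (q_reference > 0 and q_improved > 0):
        raise ValueError("qualities must be > 0")
    return q_improved / q_reference
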