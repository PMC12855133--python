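"""Predator-prey dynamics of planning workload and staff pressure.

The treatment-planning backlog Np (number of plans awaiting work, the "prey")
and the pressure P on the planning staff (the "predator") are coupled by

    dNp/dt =  a*Np - b*Np*P
    dP/dt  = -c*P  + d*b*Np*P

with a the plan-generation rate, b the per-plan pressure coupling, c the
natural pressure-decay rate and d the pressure-growth scaling. Performance is
read out as e*b*Np*P with performance coefficient e. The system has the
extinction equilibrium (0, 0) and an interior equilibrium (c/(d*b), a/b)
around which both quantities oscillate: pressure raises throughput, which
drains the backlog, which lets pressure relax — a balancing loop that no
straight-line workload->performance model reproduces.

Like the classical two-species system, the flow conserves

    V(Np, P) = d*b*Np - c*ln(Np) + b*P - a*ln(P),

which serves as a built-in integration-accuracy oracle: along an exact
trajectory V is constant, so its drift bounds the numerical error.

Integration is classical fixed-step fourth-order Runge-Kutta, chosen over
adaptive stepping for bit-reproducibility of the demonstration runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LVParams",
    "LVState",
    "LVTrajectory",
    "IntegrationOverflowError",
    "lv_derivatives",
    "integrate_lv",
    "conserved_quantity",
    "performance_series",
    "linear_baseline",
    "DEMO_PARAMS",
    "DEMO_INITIAL",
]


@dataclass(frozen=True)
class LVParams:
    """Model coefficients; all must be positive.

    a: plan-generation rate (1/time); b: pressure increase per plan;
    c: natural pressure decay (1/time); d: pressure-growth scaling;
    e: performance coefficient. Time units are arbitrary but consistent.
    """

    a: float
    b: float
    c: float
    d: float
    e: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0")

    @property
    def interior_equilibrium(self) -> tuple[float, float]:
        return (self.c / (self.d * self.b), self.a / self.b)


@dataclass(frozen=True)
class LVState:
    Np: float
    P: float
    t: float = 0.0


class IntegrationOverflowError(RuntimeError):
    pass


@dataclass
class LVTrajectory:
    """Uniformly spaced RK4 trajectory with the performance read-out."""

    t: np.ndarray
    Np: np.ndarray
    P: np.ndarray
    params: LVParams
    dt: float

    @property
    def performance(self) -> np.ndarray:
        return self.params.e * self.params.b * self.Np * self.P

    def states(self):
        for ti, npi, pi in zip(self.t, self.Np, self.P):
            yield LVState(Np=float(npi), P=float(pi), t=float(ti))


def lv_derivatives(
    state: LVState,
    params: LVParams,
    calendar_amplitude: float = 0.0,
    calendar_period: float = 7.0,
) -> tuple[float, float]:
    """(dNp/dt, dP/dt) at a state; exact evaluation of the two rate laws.

    With ``calendar_amplitude`` > 0 the plan-generation rate is modulated as
    a(t) = a * (1 + amplitude * sin(2*pi*t/period)), an optional stand-in for
    weekly/seasonal workload rhythm. Default off.
    """
    a = params.a
    if calendar_amplitude:
        a = a * (1.0 + calendar_amplitude * math.sin(2.0 * math.pi * state.t / calendar_period))
    dnp = a * state.Np - params.b * state.Np * state.P
    dp = -params.c * state.P + params.d * params.b * state.Np * state.P
    return dnp, dp


def integrate_lv(
    initial: LVState,
    params: LVParams,
    t_end: float,
    dt: float,
    calendar_amplitude: float = 0.0,
    calendar_period: float = 7.0,
) -> LVTrajectory:
    """Classical fixed-step RK4 from ``initial.t`` to ``t_end``."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end <= initial.t:
        raise ValueError("t_end must exceed the initial time")
    n_steps = int(round((t_end - initial.t) / dt))
    t = initial.t + dt * np.arange(n_steps + 1)
    np_arr = np.empty(n_steps + 1)
    p_arr = np.empty(n_steps + 1)
    np_arr[0], p_arr[0] = initial.Np, initial.P

    def f(ti: float, x: float, y: float) -> tuple[float, float]:
        return lv_derivatives(
            LVState(Np=x, P=y, t=ti), params, calendar_amplitude, calendar_period
        )

    x, y = initial.Np, initial.P
    for i in range(n_steps):
        ti = float(t[i])
        k1x, k1y = f(ti, x, y)
        k2x, k2y = f(ti + dt / 2, x + dt / 2 * k1x, y + dt / 2 * k1y)
        k3x, k3y = f(ti + dt / 2, x + dt / 2 * k2x, y + dt / 2 * k2y)
        k4x, k4y = f(ti + dt, x + dt * k3x, y + dt * k3y)
        x = x + dt / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
        y = y + dt / 6 * (k1y + 2 * k2y + 2 * k3y + k4y)
        if not (math.isfinite(x) and math.isfinite(y)):
            raise IntegrationOverflowError(
                f"state became non-finite at step {i + 1} (t={ti + dt:g})"
            )
        np_arr[i + 1], p_arr[i + 1] = x, y
    return LVTrajectory(t=t, Np=np_arr, P=p_arr, params=params, dt=dt)


def conserved_quantity(state: LVState, params: LVParams) -> float:
    """First integral V = d*b*Np - c*ln(Np) + b*P - a*ln(P).

    Constant along exact trajectories; minimized at the interior equilibrium.
    Requires Np > 0 and P > 0.
    """
    if state.Np <= 0 or state.P <= 0:
        raise ValueError("conserved quantity defined only for Np > 0 and P > 0")
    return (
        params.d * params.b * state.Np
        - params.c * math.log(state.Np)
        + params.b * state.P
        - params.a * math.log(state.P)
    )


def performance_series(traj: LVTrajectory) -> list[tuple[float, float]]:
    """Pointwise (t, e*b*Np*P) along a trajectory."""
    if traj.t.size == 0:
        raise ValueError("empty trajectory")
    return list(zip(traj.t.tolist(), traj.performance.tolist()))


def linear_baseline(pressure: Sequence[float], slope: float) -> np.ndarray:
    """The straight-line contrast: Performance = slope * P, no feedback."""
    if slope <= 0:
        raise ValueError("slope must be > 0")
    return slope * np.asarray(pressure, dtype=float)


#: Illustrative demonstration scenario (the model is qualitative; no
#: empirical parameter values exist for it).
DEMO_PARAMS = LVParams(a=1.0, b=0.5, c=1.0, d=0.5, e=1.0)
DEMO_INITIAL = LVState(Np=2.0, P=1.0, t=0.0)
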