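"""Multi-loop feedback simulation of pressure, performance, errors,
work remaining, and patient satisfaction.

The model realizes, as discrete fixed-step updates, the causal loops of a
treatment-planning sub-system: pressure drives performance, performance burns
down the remaining work, but pressure also raises the per-step error
probability; errors create rework (raising the work remaining) and erode
patient satisfaction; satisfaction feeds the arrival of new patients, which
adds work; and the work remaining in turn sets the pressure. One step applies,
in this order:

    p_err   = min(1, error_rate * Pr)
    err     = Bernoulli(p_err)            (stochastic mode)
            = p_err                       (expectation mode)
    Perf'   = f0 * Pr
    done    = kappa * Perf' * dt
    arrive  = lam * S * dt
    W'      = max(0, W - done + rho * err + arrive)
    Pr'     = clamp(pi * W' / W_ref, 0, Pr_max)
    S'      = clamp(S - sigma*err*dt + gamma*(1 - S)*(1 - err)*dt, 0, 1)

Expectation mode replaces the Bernoulli draw by its probability, giving a
deterministic skeleton of the stochastic model (a mean-field approximation:
the clamps and the state-dependence of p_err make the stochastic mean differ
from it at higher error rates). Clamps keep S in [0, 1], Pr in [0, Pr_max]
and W >= 0 for every parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "FeedbackParams",
    "FeedbackState",
    "SimTrajectory",
    "step",
    "run_simulation",
    "summarize",
]


@dataclass(frozen=True)
class FeedbackParams:
    """Simulation parameters.

    The defaults are order-unity coefficients around the normalized initial
    state (pressure = performance = satisfaction = 1): per-step error
    probability scale ``error_rate`` = 0.1, horizon ``T`` = 20 steps of
    ``dt`` = 1, initial work ``W0`` = ``W_ref`` = 10.
    """

    error_rate: float = 0.1
    T: int = 20
    dt: float = 1.0
    W0: float = 10.0
    perf_gain: float = 1.0  # f0
    completion: float = 0.5  # kappa
    rework: float = 1.0  # rho
    arrival: float = 0.5  # lam
    pressure_scale: float = 1.0  # pi
    W_ref: float = 10.0
    satisfaction_loss: float = 0.5  # sigma
    satisfaction_recovery: float = 0.1  # gamma
    Pr_max: float = 5.0
    mode: str = "stochastic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.Pr_max <= 0:
            raise ValueError("Pr_max must be > 0")
        for name in (
            "W0",
            "perf_gain",
            "completion",
            "rework",
            "arrival",
            "pressure_scale",
            "W_ref",
            "satisfaction_loss",
            "satisfaction_recovery",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mode not in ("stochastic", "expectation"):
            raise ValueError("mode must be 'stochastic' or 'expectation'")


@dataclass(frozen=True)
class FeedbackState:
    t: int = 0
    pressure: float = 1.0
    performance: float = 1.0
    work_remaining: float = 10.0
    satisfaction: float = 1.0
    errors_this_step: float = 0.0
    cumulative_errors: float = 0.0
    arrivals_this_step: float = 0.0


@dataclass
class SimTrajectory:
    states: list[FeedbackState]
    params: FeedbackParams

    def __len__(self) -> int:
        return len(self.states)

    def array(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.states])


def _clamp(x: float, lo: float, hi: float) -> float:
    return min(hi, max(lo, x))


def step(
    state: FeedbackState,
    params: FeedbackParams,
    rng: np.random.Generator | None = None,
) -> FeedbackState:
    """Advance the coupled system by one time step.

    In stochastic mode ``rng`` supplies the Bernoulli error draw; expectation
    mode needs no randomness and uses the error probability directly.
    """
    p_err = min(1.0, params.error_rate * state.pressure)
    if params.mode == "stochastic":
        if rng is None:
            raise ValueError("stochastic mode requires an rng")
        err = float(rng.random() < p_err)
    else:
        err = p_err
    perf = params.perf_gain * state.pressure
    completed = params.completion * perf * params.dt
    arrivals = params.arrival * state.satisfaction * params.dt
    w = max(0.0, state.work_remaining - completed + params.rework * err + arrivals)
    pr = _clamp(params.pressure_scale * w / params.W_ref, 0.0, params.Pr_max)
    s = _clamp(
        state.satisfaction
        - params.satisfaction_loss * err * params.dt
        + params.satisfaction_recovery * (1.0 - state.satisfaction) * (1.0 - err) * params.dt,
        0.0,
        1.0,
    )
    return FeedbackState(
        t=state.t + 1,
        pressure=pr,
        performance=perf,
        work_remaining=w,
        satisfaction=s,
        errors_this_step=err,
        cumulative_errors=state.cumulative_errors + err,
        arrivals_this_step=arrivals,
    )


def run_simulation(params: FeedbackParams) -> SimTrajectory:
    """Run T steps from the normalized initial state (Pr = Perf = S = 1).

    Stochastic runs are reproducible from ``params.seed``; expectation runs
    are deterministic.
    """
    rng = np.random.default_rng(params.seed) if params.mode == "stochastic" else None
    state = FeedbackState(
        t=0,
        pressure=1.0,
        performance=1.0,
        work_remaining=params.W0,
        satisfaction=1.0,
    )
    states = [state]
    for _ in range(params.T):
        state = step(state, params, rng)
        states.append(state)
    return SimTrajectory(states=states, params=params)


def summarize(traj: SimTrajectory) -> dict:
    """Headline trade-off numbers of one run."""
    if not traj.states:
        raise ValueError("empty trajectory")
    return {
        "final_S": traj.states[-1].satisfaction,
        "mean_Perf": float(traj.array("performance").mean()),
        "total_errors": traj.states[-1].cumulative_errors,
        "peak_W": float(traj.array("work_remaining").max()),
        "peak_Pr": float(traj.array("pressure").max()),
    }
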