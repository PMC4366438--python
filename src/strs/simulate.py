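"""Numerical integration of the smooth and impulsively pulsed STRS models.

The smooth flow is integrated on the reduced (S, T) system with
R = total - S - T, which conserves the population total exactly by
construction.  Impulses ("direct route to righteousness" assembly pulses)
move a proportion ``p`` of susceptibles to the righteous class at times
t = first_pulse_time + k*tau; they are implemented by stop-restart
integration at the pulse instants with bit-exact pulse arithmetic, never by
smoothing the Dirac delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    InsufficientSpanError,
    IntegrationFailureError,
    InvalidParameterError,
)
from .models import (
    CompartmentState,
    PredatorPreyParams,
    PredatorPreyState,
    STRSParams,
)

__all__ = [
    "PulseSchedule",
    "PulseEvent",
    "Trajectory",
    "integrate",
    "apply_pulse",
    "integrate_pulsed",
    "integrate_predator_prey",
    "periodic_steady_state_average",
]

DEFAULT_RTOL = 1e-10
DEFAULT_ATOL = 1e-12
#: Solver undershoot below zero larger than this (times the population scale)
#: is treated as an integration failure rather than silently clamped.
_CLAMP_LIMIT = 1e-9


@dataclass(frozen=True)
class PulseSchedule:
    """Assembly-pulse schedule: proportion ``p`` of susceptibles moved to the
    righteous class every ``tau`` weeks, first pulse at ``first_pulse_time``
    (default tau, so the stated initial condition is the pre-assembly state).
    """

    p: float
    tau: float
    first_pulse_time: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise InvalidParameterError("pulse proportion p must lie in [0, 1]")
        if not self.tau > 0:
            raise InvalidParameterError("pulse interval tau must be positive")
        if self.first_pulse_time is None:
            object.__setattr__(self, "first_pulse_time", self.tau)

    def times_in(self, t_start: float, t_end: float) -> np.ndarray:
        """Pulse instants within [t_start, t_end] (inclusive on both ends)."""
        first = float(self.first_pulse_time)
        if first > t_end:
            return np.array([])
        k0 = max(0, int(np.ceil((t_start - first) / self.tau - 1e-12)))
        ks = np.arange(k0, int(np.floor((t_end - first) / self.tau + 1e-12)) + 1)
        return first + self.tau * ks


@dataclass(frozen=True)
class PulseEvent:
    """One impulse: the instant plus the states immediately before and after."""

    time: float
    before: CompartmentState
    after: CompartmentState


@dataclass
class Trajectory:
    """Time grid and compartment series, with pulse-event annotations.

    ``times`` is strictly increasing; at a pulse instant the grid point holds
    the pre-pulse (left-limit) state and the corresponding
    :class:`PulseEvent` records both one-sided values.
    """

    times: np.ndarray
    S: np.ndarray
    T: np.ndarray
    R: np.ndarray
    pulse_events: list[PulseEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("trajectory times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def total(self) -> np.ndarray:
        return self.S + self.T + self.R

    def state_at(self, i: int) -> CompartmentState:
        return CompartmentState(S=self.S[i], T=self.T[i], R=self.R[i])

    @property
    def final_state(self) -> CompartmentState:
        return self.state_at(-1)

    def conservation_drift(self) -> float:
        """Max relative deviation of S+T+R from its initial value."""
        total0 = self.total[0]
        return float(np.max(np.abs(self.total - total0)) / total0)


def _clamp(values: np.ndarray, scale: float) -> np.ndarray:
    """Zero out tiny solver undershoot; fail loudly on anything larger."""
    worst = values.min(initial=0.0)
    if worst < -_CLAMP_LIMIT * scale:
        raise IntegrationFailureError(
            f"compartment undershoot {worst:.3e} exceeds the clamp limit"
        )
    return np.where(values < 0.0, 0.0, values)


def integrate(
    params: STRSParams,
    init: CompartmentState,
    t_span: tuple[float, float],
    *,
    t_eval: np.ndarray | None = None,
    points_per_week: float = 20.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the smooth STRS flow over ``t_span`` weeks.

    The output grid is ``t_eval`` if given, else equispaced at
    ``points_per_week``.  An empty span returns the single-point trajectory
    equal to ``init``.  Solver failure raises
    :class:`IntegrationFailureError` carrying the last good time.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 < t0:
        raise InvalidParameterError("t_span end must be >= start")
    total = init.total
    scale = max(params.N, total)
    if t1 == t0:
        return Trajectory(
            times=np.array([t0]),
            S=np.array([init.S]),
            T=np.array([init.T]),
            R=np.array([init.R]),
        )
    if t_eval is None:
        n = max(2, int(round((t1 - t0) * points_per_week)) + 1)
        t_eval = np.linspace(t0, t1, n)

    alpha, beta, N = params.alpha, params.beta, params.N
    forcing = params.forcing

    def rhs(t, y):
        S, T = y
        gamma = forcing.rate(t)
        contagion = beta * S * T / N
        return (alpha * (total - S - T) - contagion, contagion - gamma * T)

    sol = solve_ivp(
        rhs,
        (t0, t1),
        [init.S, init.T],
        method=method,
        t_eval=np.asarray(t_eval, dtype=float),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else t0
        raise IntegrationFailureError(
            f"ODE solver failed at t = {last:.6g}: {sol.message}", last_good_time=last
        )
    S = _clamp(sol.y[0], scale)
    T = _clamp(sol.y[1], scale)
    R = _clamp(total - S - T, scale)
    return Trajectory(times=sol.t, S=S, T=T, R=R)


def apply_pulse(state: CompartmentState, p: float) -> CompartmentState:
    """Move the proportion ``p`` of susceptibles to the righteous class.

    S' = (1-p)*S, R' = R + p*S, T unchanged; the total is conserved exactly
    (the same product p*S is subtracted and added).
    """
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError("pulse proportion p must lie in [0, 1]")
    moved = p * state.S
    return CompartmentState(S=state.S - moved, T=state.T, R=state.R + moved)


def integrate_pulsed(
    params: STRSParams,
    pulses: PulseSchedule,
    init: CompartmentState,
    t_span: tuple[float, float],
    *,
    points_per_week: float = 20.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "RK45",
) -> Trajectory:
    """Integrate the pulsed STRS model: smooth flow between assembly pulses.

    Pulse instants inside ``t_span`` land exactly on the output grid; the
    grid point holds the left limit and the matching :class:`PulseEvent`
    records both one-sided states.  A pulse scheduled exactly at the start
    of the span is applied to ``init`` before any integration.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 < t0:
        raise InvalidParameterError("t_span end must be >= start")
    pulse_times = list(pulses.times_in(t0, t1))
    events: list[PulseEvent] = []

    state = init
    if pulse_times and abs(pulse_times[0] - t0) <= 1e-12 * max(1.0, abs(t0)):
        after = apply_pulse(state, pulses.p)
        events.append(PulseEvent(time=t0, before=state, after=after))
        state = after
        pulse_times = pulse_times[1:]

    # every breakpoint except a possibly-appended trailing t1 is a pulse
    breakpoints = pulse_times + ([t1] if not pulse_times or pulse_times[-1] < t1 else [])
    times_parts: list[np.ndarray] = []
    parts: dict[str, list[np.ndarray]] = {"S": [], "T": [], "R": []}
    seg_start = t0
    for i, seg_end in enumerate(breakpoints):
        seg = integrate(
            params,
            state,
            (seg_start, seg_end),
            points_per_week=points_per_week,
            rtol=rtol,
            atol=atol,
            method=method,
        )
        lo = 0 if i == 0 else 1  # drop the duplicated segment-start point
        times_parts.append(seg.times[lo:])
        for key in parts:
            parts[key].append(getattr(seg, key)[lo:])
        state = seg.final_state
        if i < len(pulse_times):
            after = apply_pulse(state, pulses.p)
            events.append(PulseEvent(time=seg_end, before=state, after=after))
            state = after
        seg_start = seg_end
    return Trajectory(
        times=np.concatenate(times_parts),
        S=np.concatenate(parts["S"]),
        T=np.concatenate(parts["T"]),
        R=np.concatenate(parts["R"]),
        pulse_events=events,
    )


def integrate_predator_prey(
    params: PredatorPreyParams,
    init: PredatorPreyState,
    t_span: tuple[float, float],
    *,
    points_per_week: float = 20.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "RK45",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate the criminal/police predator-prey system.

    Returns (times, x, y).  Orbits of this system are closed curves on which
    c*x - d*ln(x) + b*y - a*ln(y) is constant, making it a sharp oracle for
    integrator quality.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    n = max(2, int(round((t1 - t0) * points_per_week)) + 1)

    def rhs(_t, z):
        x, y = z
        return (params.a * x - params.b * x * y, params.c * x * y - params.d * y)

    sol = solve_ivp(
        rhs,
        (t0, t1),
        [init.x, init.y],
        method=method,
        t_eval=np.linspace(t0, t1, n),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationFailureError(f"ODE solver failed: {sol.message}")
    return sol.t, sol.y[0], sol.y[1]


def periodic_steady_state_average(
    traj: Trajectory, period: float, n_periods: int
) -> tuple[float, float, float]:
    """Time-averaged (S, T, R) over the last ``n_periods * period`` weeks.

    Averages are trapezoidal integrals over the terminal window divided by
    its length; the window's left endpoint is linearly interpolated onto the
    grid.  Raises :class:`InsufficientSpanError` if the trajectory is shorter
    than the window.
    """
    if period <= 0 or n_periods <= 0:
        raise InvalidParameterError("period and n_periods must be positive")
    window = period * n_periods
    t_end = traj.times[-1]
    t_start = t_end - window
    if t_start < traj.times[0] - 1e-9 * max(1.0, window):
        raise InsufficientSpanError(
            f"averaging window {window:.6g} weeks exceeds trajectory span "
            f"{t_end - traj.times[0]:.6g} weeks"
        )
    t_start = max(t_start, traj.times[0])
    mask = traj.times > t_start
    t = np.concatenate([[t_start], traj.times[mask]])
    means = []
    for series in (traj.S, traj.T, traj.R):
        y0 = np.interp(t_start, traj.times, series)
        y = np.concatenate([[y0], series[mask]])
        means.append(float(np.trapezoid(y, t) / (t[-1] - t_start)))
    return tuple(means)  # type: ignore[return-value]
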