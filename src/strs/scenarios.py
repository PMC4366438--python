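"""Named parameter fixtures for the published simulations, plus a seeded
random-scenario generator for property testing.

Each named scenario bundles the exact printed parameter set of one published
simulation (the two transgression-wave panels with and without sinusoidal
forcing, the fortnightly/weekly/biannual assembly-pulse runs, and the
heroin-contagion calibration), together with its initial state, default
horizon, and a provenance string.

The transgression-wave panels are specified only through the dimensionless
indices (Basic Sabbath Number and cohesion factor); absolute rates are fixed
by the modelling convention gamma = 1 per week (one-week average transgressor
lifetime), which each fixture's provenance records.

The heroin calibration inserts N = 50 with S0 = 50 and T0 = 1 — a total of
51 with a contact divisor of 50 — exactly as printed; the conserved quantity
along that trajectory is the total 51, not N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, NotReachedError, UnknownScenarioError
from .models import CompartmentState, RepentanceForcing, STRSParams, TWO_PI
from .simulate import PulseSchedule, Trajectory

__all__ = [
    "Scenario",
    "SCENARIO_NAMES",
    "named_scenario",
    "heroin_conversion_times",
    "random_scenario",
]


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation: parameters, optional pulse schedule,
    initial state, default horizon in weeks, and a provenance citation."""

    name: str
    params: STRSParams
    init: CompartmentState
    horizon: float
    provenance: str
    pulses: PulseSchedule | None = None


def _fig2(name: str, shin0: float, sinusoidal: bool) -> Scenario:
    gamma = 1.0  # one-week average transgressor lifetime fixes the rate scale
    beta = gamma / shin0
    alpha = gamma / 0.4  # cohesion factor 0.4
    forcing = (
        RepentanceForcing(kind="sinusoidal", mean=gamma, amplitude=gamma)
        if sinusoidal
        else RepentanceForcing(mean=gamma)
    )
    variant = "periodic gamma(t) = 1 + sin(2*pi*t)" if sinusoidal else "constant gamma"
    return Scenario(
        name=name,
        params=STRSParams(alpha=alpha, beta=beta, forcing=forcing, N=100.0),
        init=CompartmentState(S=95.0, T=5.0, R=0.0),
        horizon=300.0,
        provenance=(
            f"transgression-wave panel, N=100, T0=5, cohesion 0.4, "
            f"Sabbath number {shin0}, {variant}; rates fixed by gamma=1/week"
        ),
    )


def _pulsed(
    name: str,
    *,
    alpha: float,
    beta: float,
    gamma: float,
    tau: float,
    p: float,
    S0: float,
    T0: float,
    horizon: float,
    provenance: str,
) -> Scenario:
    return Scenario(
        name=name,
        params=STRSParams.with_constant_gamma(alpha, beta, gamma, N=1.0),
        init=CompartmentState(S=S0, T=T0, R=1.0 - S0 - T0),
        pulses=PulseSchedule(p=p, tau=tau),
        horizon=horizon,
        provenance=provenance,
    )


def _build_registry() -> dict[str, Scenario]:
    reg = {
        "fig2a_i": _fig2("fig2a_i", shin0=0.6, sinusoidal=False),
        "fig2a_ii": _fig2("fig2a_ii", shin0=1.1, sinusoidal=False),
        "fig2b_i": _fig2("fig2b_i", shin0=0.6, sinusoidal=True),
        "fig2b_ii": _fig2("fig2b_ii", shin0=1.1, sinusoidal=True),
        "fig4": _pulsed(
            "fig4",
            alpha=0.63,
            beta=1.5,
            gamma=0.9,
            tau=2.0,
            p=0.5,
            S0=0.1,
            T0=0.01,
            horizon=300.0,
            provenance="fortnightly assembly pulses; transgressors persist",
        ),
        "fig5": _pulsed(
            "fig5",
            alpha=0.63,
            beta=1.5,
            gamma=0.9,
            tau=1.0,
            p=0.5,
            S0=0.1,
            T0=0.01,
            horizon=300.0,
            provenance="weekly assembly pulses; transgressors die out",
        ),
        "fig6": _pulsed(
            "fig6",
            alpha=0.00027,
            beta=10.0,
            gamma=1.0,
            tau=104.0,
            p=0.1,
            S0=0.1,
            T0=0.0001,
            horizon=50.0 * 104.0,
            provenance=(
                "biannual assembly pulses, complex oscillatory regime; "
                "parameter-list values used (p=0.1)"
            ),
        ),
        "heroin": Scenario(
            name="heroin",
            params=STRSParams.with_constant_gamma(0.0, 1.46, 0.0, N=50.0),
            init=CompartmentState(S=50.0, T=1.0, R=0.0),
            horizon=10.0,
            provenance=(
                "heroin-addiction contagion calibration: N=50 contact divisor, "
                "S0=50, T0=1, beta=1.46, alpha=gamma=0 (printed values verbatim)"
            ),
        ),
    }
    return reg


_REGISTRY = _build_registry()
SCENARIO_NAMES = tuple(sorted(_REGISTRY))


def named_scenario(name: str) -> Scenario:
    """Look up one of the published-simulation fixtures by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnknownScenarioError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIO_NAMES)}"
        ) from None


def _first_crossing(traj: Trajectory, level: float, what: str) -> float:
    """First time T reaches ``level``, linearly interpolated between grid points."""
    T = traj.T
    if T[0] >= level:
        return float(traj.times[0])
    above = np.nonzero(T >= level)[0]
    if above.size == 0:
        raise NotReachedError(
            f"{what}: T never reaches {level:.6g} within the horizon "
            f"(max {T.max():.6g})"
        )
    i = int(above[0])
    t0, t1 = traj.times[i - 1], traj.times[i]
    y0, y1 = T[i - 1], T[i]
    return float(t0 + (level - y0) * (t1 - t0) / (y1 - y0))


def heroin_conversion_times(
    traj: Trajectory,
    half_level: float = 25.0,
    near_total_level: float = 50.0,
) -> tuple[float, float]:
    """(t_half, t_total): first times T reaches the half- and near-total levels.

    For the heroin fixture (51 individuals, one initial addict) the defaults
    are 25 addicts and 50 addicts.  Crossing times are linearly interpolated;
    a level never reached raises :class:`NotReachedError`.
    """
    t_half = _first_crossing(traj, half_level, "half conversion")
    t_total = _first_crossing(traj, near_total_level, "near-total conversion")
    return t_half, t_total


def random_scenario(
    seed: int | np.random.Generator,
    sabbath_range: tuple[float, float] = (0.5, 1.5),
    cohesion_range: tuple[float, float] = (0.25, 4.0),
    N: float = 100.0,
    sinusoidal: bool = False,
) -> Scenario:
    """Deterministic random scenario for property tests.

    Fixes gamma_bar = 1 per week, draws the Basic Sabbath Number and the
    cohesion factor uniformly from the requested ranges (setting beta and
    alpha), optionally draws a sinusoidal amplitude uniformly from
    [0, gamma_bar] so the forcing nonnegativity invariant holds by
    construction, and seeds a 5% transgressor perturbation.
    """
    for lo, hi in (sabbath_range, cohesion_range):
        if not (0 < lo <= hi):
            raise InvalidParameterError("ranges must be positive and nondecreasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gamma = 1.0
    shin0 = rng.uniform(*sabbath_range)
    cohesion = rng.uniform(*cohesion_range)
    beta = gamma / shin0
    alpha = gamma / cohesion
    if sinusoidal:
        forcing = RepentanceForcing(
            kind="sinusoidal",
            mean=gamma,
            amplitude=rng.uniform(0.0, gamma),
            angular_frequency=TWO_PI,
        )
    else:
        forcing = RepentanceForcing(mean=gamma)
    T0 = 0.05 * N
    return Scenario(
        name=f"random-{shin0:.4f}-{cohesion:.4f}",
        params=STRSParams(alpha=alpha, beta=beta, forcing=forcing, N=N),
        init=CompartmentState(S=N - T0, T=T0, R=0.0),
        horizon=200.0,
        provenance="seeded random scenario (property testing)",
    )
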