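"""Parameter/state containers and right-hand sides for the STRS model family.

The STRS model partitions a closed community of size ``N`` into susceptibles
``S`` (who may be corrupted), transgressors ``T`` (who violate the shared
normative code), and righteous ``R`` (who obey it).  Structurally it is an
SIRS epidemic model in which infection is norm violation at contact rate
``beta``, recovery is repentance at rate ``gamma`` (possibly time-periodic,
representing a weekly assembly), and loss of immunity is lapse at rate
``alpha``:

    dS/dt = alpha*R - beta*S*T/N
    dT/dt = beta*S*T/N - gamma(t)*T
    dR/dt = gamma(t)*T - alpha*R

The three derivatives sum to zero, so the total population is conserved.
Time is measured in weeks throughout; the default forcing period is one week
(angular frequency 2*pi per week).

A two-compartment predator-prey model of criminals ``x`` versus police ``y``
is included as the classical stratified-society baseline the STRS model is
contrasted against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidForcingError, InvalidParameterError

__all__ = [
    "PredatorPreyParams",
    "PredatorPreyState",
    "RepentanceForcing",
    "STRSParams",
    "CompartmentState",
    "repentance_rate_at",
    "strs_derivatives",
    "strs_reduced_derivatives",
    "predator_prey_derivatives",
    "predator_prey_invariant",
]

TWO_PI = 2.0 * math.pi

#: Number of equispaced samples per period used to certify gamma(t) >= 0.
_FORCING_SAMPLES = 1000


@dataclass(frozen=True)
class PredatorPreyParams:
    """Rates of the criminal/police predator-prey model (all per week, > 0).

    ``a``: criminal per-capita growth; ``b``: removal of criminals per police
    contact; ``c``: police growth per criminal contact; ``d``: police decline.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")

    @property
    def coexistence_equilibrium(self) -> "PredatorPreyState":
        """The positive fixed point x* = d/c, y* = a/b."""
        return PredatorPreyState(x=self.d / self.c, y=self.a / self.b)


@dataclass(frozen=True)
class PredatorPreyState:
    """Criminal count ``x`` and police count ``y``, both nonnegative."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise InvalidParameterError("x and y must be nonnegative")


@dataclass(frozen=True)
class RepentanceForcing:
    """Time profile of the repentance rate gamma(t), in events per week.

    kind
        ``"constant"``: gamma(t) = ``mean`` for all t.
        ``"sinusoidal"``: gamma(t) = mean + amplitude*sin(omega*t).
        ``"fourier"``: gamma(t) = mean + Re(sum_n harmonics[n-1]*exp(i*n*omega*t)).
        The complex amplitude convention means a pure sine of amplitude
        ``delta`` is the single harmonic ``-1j*delta``.
    mean
        Time-average rate gamma-bar (>= 0).  1/mean is the average residence
        time in the transgressor class.
    amplitude
        Forcing amplitude delta for the sinusoidal kind (0 <= delta <= mean,
        which suffices for nonnegativity).
    harmonics
        Complex amplitudes (gamma_1, gamma_2, ...) for the fourier kind.
    angular_frequency
        omega in radians per week; default 2*pi (one-week period).

    Nonnegativity of gamma(t) is certified at construction by sampling 1000
    equispaced points over one full period; a forcing that dips negative
    raises :class:`InvalidForcingError` immediately, never at evaluation.
    """

    kind: str = "constant"
    mean: float = 1.0
    amplitude: float = 0.0
    harmonics: tuple[complex, ...] = ()
    angular_frequency: float = TWO_PI

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoidal", "fourier"):
            raise InvalidParameterError(f"unknown forcing kind {self.kind!r}")
        if self.mean < 0:
            raise InvalidForcingError("mean repentance rate must be nonnegative")
        if self.angular_frequency <= 0:
            raise InvalidParameterError("angular_frequency must be positive")
        if self.kind == "sinusoidal":
            if self.amplitude < 0:
                raise InvalidForcingError("amplitude must be nonnegative")
            if self.amplitude > self.mean + 1e-12:
                raise InvalidForcingError(
                    "sinusoidal amplitude exceeds mean: gamma(t) would be negative"
                )
        # freeze harmonics into a hashable tuple even if a list was passed
        object.__setattr__(self, "harmonics", tuple(self.harmonics))
        if self.kind == "fourier":
            t = np.linspace(0.0, self.period, _FORCING_SAMPLES, endpoint=False)
            if np.min(self.rate(t)) < -1e-12:
                raise InvalidForcingError(
                    "fourier forcing is negative somewhere over one period"
                )

    @property
    def period(self) -> float:
        """Fundamental period 2*pi/omega in weeks."""
        return TWO_PI / self.angular_frequency

    @property
    def is_periodic(self) -> bool:
        return self.kind != "constant" and (
            self.amplitude != 0 or any(h != 0 for h in self.harmonics)
        )

    def rate(self, t):
        """Evaluate gamma(t); accepts scalars or arrays (weeks)."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            out = np.full_like(t, self.mean)
        elif self.kind == "sinusoidal":
            out = self.mean + self.amplitude * np.sin(self.angular_frequency * t)
        else:
            out = np.full_like(t, self.mean)
            for n, gamma_n in enumerate(self.harmonics, start=1):
                out = out + np.real(
                    gamma_n * np.exp(1j * n * self.angular_frequency * t)
                )
        return out if out.ndim else float(out)


def repentance_rate_at(forcing: RepentanceForcing, t: float) -> float:
    """gamma(t) in events per week at time ``t`` weeks."""
    return forcing.rate(t)


@dataclass(frozen=True)
class STRSParams:
    """Rates and population size of the STRS model.

    ``alpha`` (lapse, per week, >= 0), ``beta`` (transgression contagiousness,
    per week, > 0), ``forcing`` (the repentance-rate profile housing gamma),
    and ``N`` (population size, > 0; use 1.0 for fraction-normalised runs).
    """

    alpha: float
    beta: float
    forcing: RepentanceForcing = field(default_factory=RepentanceForcing)
    N: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise InvalidParameterError("alpha must be nonnegative")
        if not self.beta > 0:
            raise InvalidParameterError("beta must be strictly positive")
        if not self.N > 0:
            raise InvalidParameterError("N must be strictly positive")

    @classmethod
    def with_constant_gamma(
        cls, alpha: float, beta: float, gamma: float, N: float = 1.0
    ) -> "STRSParams":
        """Convenience constructor for the unforced (constant-gamma) model."""
        return cls(alpha=alpha, beta=beta, forcing=RepentanceForcing(mean=gamma), N=N)

    @property
    def gamma_mean(self) -> float:
        """gamma-bar, the time-average repentance rate."""
        return self.forcing.mean

    def gamma_at(self, t: float) -> float:
        return self.forcing.rate(t)


@dataclass(frozen=True)
class CompartmentState:
    """Point-in-time compartment occupancies (S, T, R), each nonnegative."""

    S: float
    T: float
    R: float

    def __post_init__(self) -> None:
        if self.S < 0 or self.T < 0 or self.R < 0:
            raise InvalidParameterError("compartment values must be nonnegative")

    @property
    def total(self) -> float:
        return self.S + self.T + self.R

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.T, self.R], dtype=float)


def strs_derivatives(
    state: CompartmentState, params: STRSParams, t: float = 0.0
) -> tuple[float, float, float]:
    """(dS/dt, dT/dt, dR/dt) of the full three-compartment system.

    The components sum to zero exactly up to floating round-off (population
    conservation).
    """
    gamma = params.gamma_at(t)
    contagion = params.beta * state.S * state.T / params.N
    lapse = params.alpha * state.R
    repentance = gamma * state.T
    return (lapse - contagion, contagion - repentance, repentance - lapse)


def strs_reduced_derivatives(
    S: float, T: float, params: STRSParams, t: float = 0.0, total: float | None = None
) -> tuple[float, float]:
    """(dS/dt, dT/dt) of the reduced two-variable system with R eliminated.

    ``total`` is the conserved population S+T+R, defaulting to ``params.N``;
    R is taken as total - S - T.
    """
    if total is None:
        total = params.N
    gamma = params.gamma_at(t)
    contagion = params.beta * S * T / params.N
    return (params.alpha * (total - S - T) - contagion, contagion - gamma * T)


def predator_prey_derivatives(
    state: PredatorPreyState, params: PredatorPreyParams
) -> tuple[float, float]:
    """(dx/dt, dy/dt) = (a*x - b*x*y, c*x*y - d*y) of the criminal/police model."""
    x, y = state.x, state.y
    return (params.a * x - params.b * x * y, params.c * x * y - params.d * y)


def predator_prey_invariant(state: PredatorPreyState, params: PredatorPreyParams) -> float:
    """First integral c*x - d*ln(x) + b*y - a*ln(y), conserved along orbits.

    Used as an integrator-quality oracle: its drift along a numerical
    trajectory measures accumulated solver error.
    """
    if state.x <= 0 or state.y <= 0:
        raise InvalidParameterError("first integral requires x > 0 and y > 0")
    return (
        params.c * state.x
        - params.d * math.log(state.x)
        + params.b * state.y
        - params.a * math.log(state.y)
    )
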