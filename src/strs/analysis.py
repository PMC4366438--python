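"""Equilibria, stability, thresholds, and bifurcation structure of the STRS model.

The unforced model has two fixed points whose stability is exchanged in a
transcritical bifurcation at the Basic Sabbath Number

    shin_0 = gamma_bar / beta = 1,

the reciprocal of the epidemiological basic reproduction number.  Above
threshold (shin_0 > 1) the transgressor-free state (S, T, R) = (N, 0, 0) is
stable; below it an endemic-transgression equilibrium

    S*/N = gamma/beta,
    T*/N = (1 - gamma/beta) / (1 + gamma/alpha),
    R*/N = (1 - gamma/beta) / (1 + alpha/gamma)

exists and is stable.  The split of the non-susceptible population between
transgressors and righteous is governed by the cohesion factor gamma/alpha.

Stability is classified on the reduced two-variable system: the full
three-compartment system carries a structural zero eigenvalue from
population conservation that would otherwise obscure the classification.

For a periodic repentance rate the transgressor-free stability is settled by
the Floquet multiplier of the linearised transgressor equation over one
period, which this module computes by direct integration and which equals
exp((beta - gamma_bar) * period) — i.e. the threshold depends only on the
mean rate, not the forcing amplitude.  For assembly pulses the threshold
criterion compares shin_0 with the susceptible proportion averaged over one
pulse cycle at the transgressor-free periodic attractor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .errors import (
    BracketError,
    ConvergenceError,
    InvalidParameterError,
    NoEndemicEquilibriumError,
)
from .models import CompartmentState, STRSParams
from .simulate import PulseSchedule

__all__ = [
    "SabbathIndices",
    "EquilibriumReport",
    "sabbath_indices",
    "reduced_jacobian",
    "transgressor_free_report",
    "endemic_report",
    "locate_transcritical",
    "bifurcation_curve",
    "floquet_multiplier",
    "pulsed_threshold_margin",
]

#: Eigenvalue real parts within this of zero classify as "neutral".
_NEUTRAL_TOL = 1e-12


@dataclass(frozen=True)
class SabbathIndices:
    """Dimensionless indices of the model.

    ``basic_sabbath_number``: gamma_bar/beta, resistance of susceptibles to
    corruption (reciprocal of R0).  ``cohesion_factor``: gamma_bar/alpha,
    +inf when alpha = 0.
    """

    basic_sabbath_number: float
    cohesion_factor: float


@dataclass(frozen=True)
class EquilibriumReport:
    """A fixed point with its local-stability verdict.

    ``eigenvalues`` are those of the reduced (S, T) Jacobian.  ``stable`` is
    True only when every real part is strictly negative; ``classification``
    distinguishes the knife-edge "neutral" case (a zero real part) from
    outright instability.
    """

    label: str  # "transgressor_free" | "endemic"
    state: CompartmentState
    eigenvalues: tuple[complex, complex]
    stable: bool
    classification: str  # "stable" | "unstable" | "neutral"
    indices: SabbathIndices


def sabbath_indices(params: STRSParams) -> SabbathIndices:
    """Basic Sabbath Number gamma_bar/beta and cohesion factor gamma_bar/alpha."""
    if not params.beta > 0:
        raise InvalidParameterError("beta must be strictly positive")
    gamma = params.gamma_mean
    cohesion = math.inf if params.alpha == 0 else gamma / params.alpha
    return SabbathIndices(
        basic_sabbath_number=gamma / params.beta, cohesion_factor=cohesion
    )


def reduced_jacobian(
    params: STRSParams, S: float, T: float, gamma: float | None = None
) -> np.ndarray:
    """Jacobian of the reduced (S, T) system at the given point.

    ``gamma`` defaults to the mean rate gamma_bar (the unforced reduction
    used throughout the fixed-point analysis).
    """
    if gamma is None:
        gamma = params.gamma_mean
    alpha, beta, N = params.alpha, params.beta, params.N
    return np.array(
        [
            [-alpha - beta * T / N, -alpha - beta * S / N],
            [beta * T / N, beta * S / N - gamma],
        ]
    )


def _classify(eigenvalues: np.ndarray) -> tuple[bool, str]:
    worst = float(np.max(eigenvalues.real))
    if worst < -_NEUTRAL_TOL:
        return True, "stable"
    if worst <= _NEUTRAL_TOL:
        return False, "neutral"
    return False, "unstable"


def transgressor_free_report(params: STRSParams) -> EquilibriumReport:
    """Report on the transgressor-free equilibrium (S, T, R) = (N, 0, 0).

    Its reduced Jacobian has eigenvalues (-alpha, beta - gamma_bar), so it is
    stable exactly when the Basic Sabbath Number exceeds one (and alpha > 0).
    """
    eig = np.linalg.eigvals(reduced_jacobian(params, S=params.N, T=0.0))
    eig = eig[np.argsort(eig.real)]
    stable, classification = _classify(eig)
    return EquilibriumReport(
        label="transgressor_free",
        state=CompartmentState(S=params.N, T=0.0, R=0.0),
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        stable=stable,
        classification=classification,
        indices=sabbath_indices(params),
    )


def endemic_report(params: STRSParams) -> EquilibriumReport:
    """Report on the endemic-transgression equilibrium (closed form).

    Exists only for shin_0 <= 1; requesting it above threshold raises
    :class:`NoEndemicEquilibriumError`.  At shin_0 = 1 it coincides with the
    transgressor-free state.  With alpha = 0 (infinite cohesion) the entire
    non-susceptible population is righteous.
    """
    idx = sabbath_indices(params)
    shin0 = idx.basic_sabbath_number
    if shin0 > 1.0 + 1e-12:
        raise NoEndemicEquilibriumError(
            f"no endemic equilibrium: Basic Sabbath Number {shin0:.6g} > 1"
        )
    N = params.N
    gamma, alpha, beta = params.gamma_mean, params.alpha, params.beta
    S_star = N * shin0
    nonsusceptible = N * (1.0 - shin0)
    if alpha == 0.0:
        T_star, R_star = 0.0, nonsusceptible
    elif gamma == 0.0:
        T_star, R_star = nonsusceptible, 0.0
    else:
        T_star = nonsusceptible / (1.0 + gamma / alpha)
        R_star = nonsusceptible / (1.0 + alpha / gamma)
    eig = np.linalg.eigvals(reduced_jacobian(params, S=S_star, T=T_star))
    eig = eig[np.argsort(eig.real)]
    stable, classification = _classify(eig)
    return EquilibriumReport(
        label="endemic",
        state=CompartmentState(S=S_star, T=T_star, R=R_star),
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        stable=stable,
        classification=classification,
        indices=idx,
    )


def locate_transcritical(
    gamma_mean: float,
    alpha: float,
    beta_range: tuple[float, float],
    *,
    tol: float = 1e-12,
) -> float:
    """Basic Sabbath Number at which the transgressor-free state loses stability.

    Scans ``beta`` over ``beta_range`` by bisection on the dominant real
    eigenvalue of the transgressor-free Jacobian and returns gamma_mean/beta
    at the zero crossing (the transcritical bifurcation; equals 1 to the
    bisection tolerance).  Raises :class:`BracketError` if the range does not
    bracket a sign change.
    """
    lo, hi = float(beta_range[0]), float(beta_range[1])
    if not (0 < lo < hi):
        raise InvalidParameterError("beta_range must be positive and increasing")

    def dominant(beta: float) -> float:
        params = STRSParams.with_constant_gamma(alpha, beta, gamma_mean, N=1.0)
        report = transgressor_free_report(params)
        return max(ev.real for ev in report.eigenvalues)

    f_lo, f_hi = dominant(lo), dominant(hi)
    if f_lo == 0.0:
        return gamma_mean / lo
    if f_hi == 0.0:
        return gamma_mean / hi
    if f_lo * f_hi > 0:
        raise BracketError(
            f"dominant eigenvalue has no sign change over beta in [{lo}, {hi}]"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = dominant(mid)
        if f_mid == 0.0 or (hi - lo) < tol * max(1.0, mid):
            return gamma_mean / mid
        if f_lo * f_mid < 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return gamma_mean / (0.5 * (lo + hi))


def bifurcation_curve(
    cohesion: float, sabbath_grid: np.ndarray, N: float = 1.0
) -> np.ndarray:
    """Endemic transgressor count T* versus the Basic Sabbath Number.

    Piecewise linear and continuous at the transcritical point:
    T*/N = (1 - shin_0)/(1 + cohesion) below threshold and 0 above.  A larger
    cohesion factor rotates the endemic branch toward the transgression-free
    axis.
    """
    grid = np.asarray(sabbath_grid, dtype=float)
    if np.any(grid < 0):
        raise InvalidParameterError("Basic Sabbath Numbers must be nonnegative")
    if cohesion < 0:
        raise InvalidParameterError("cohesion factor must be nonnegative")
    if math.isinf(cohesion):
        return np.zeros_like(grid)
    branch = N * (1.0 - grid) / (1.0 + cohesion)
    return np.where(grid < 1.0, branch, 0.0)


def floquet_multiplier(
    params: STRSParams,
    *,
    rtol: float = 1e-12,
    atol: float = 1e-14,
) -> float:
    """Dominant Floquet multiplier of the transgressor linearisation.

    Integrates T' = (beta - gamma(t)) T over one forcing period from T = 1;
    the result is the monodromy (period-advance) factor, and the
    transgressor-free state of the forced model is stable iff it is below 1.
    Because only the time average of gamma survives the integral, the
    multiplier equals exp((beta - gamma_bar) * period) independently of the
    forcing amplitude — the forced threshold coincides with the unforced one.
    For constant forcing the period is taken as 2*pi/omega as well (1 week at
    the default omega).
    """
    period = params.forcing.period
    beta, forcing = params.beta, params.forcing

    def rhs(t, y):
        return [(beta - forcing.rate(t)) * y[0]]

    sol = solve_ivp(rhs, (0.0, period), [1.0], method="DOP853", rtol=rtol, atol=atol)
    if not sol.success:
        raise ConvergenceError(f"Floquet integration failed: {sol.message}")
    return float(sol.y[0, -1])


def pulsed_threshold_margin(
    params: STRSParams,
    pulses: PulseSchedule,
    *,
    max_cycles: int = 100,
    cycle_tol: float = 1e-10,
    n_quadrature: int = 2001,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> float:
    """Threshold margin shin_0 - s_bar of the pulsed model.

    Simulates the transgressor-free pulsed susceptible dynamics
    (dS/dt = alpha (N - S), S -> (1-p) S every tau weeks) until the pulse
    cycle reaches its periodic attractor, computes the mean susceptible
    proportion s_bar over one cycle by trapezoidal quadrature, and returns
    shin_0 - s_bar.  A positive margin predicts transgressor extinction, a
    negative one persistence.  With p = 0 the attractor is S = N, so the
    margin reduces to the unforced criterion shin_0 - 1.

    Raises :class:`ConvergenceError` if the cycle map has not contracted to
    ``cycle_tol`` (relative to N) within ``max_cycles`` iterations.
    """
    if params.forcing.is_periodic:
        raise InvalidParameterError(
            "pulsed threshold margin is defined for constant repentance forcing"
        )
    alpha, N, tau, p = params.alpha, params.N, pulses.tau, pulses.p
    shin0 = sabbath_indices(params).basic_sabbath_number

    def flow(s_start: float, t_eval: np.ndarray | None = None):
        sol = solve_ivp(
            lambda _t, y: [alpha * (N - y[0])],
            (0.0, tau),
            [s_start],
            method="DOP853",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise ConvergenceError(f"pulse-cycle integration failed: {sol.message}")
        return sol

    # cycle map on the post-pulse susceptible value, starting from S = N
    s_plus = (1.0 - p) * N
    converged = False
    for _ in range(max_cycles):
        s_minus = float(flow(s_plus).y[0, -1])
        s_plus_next = (1.0 - p) * s_minus
        if abs(s_plus_next - s_plus) < cycle_tol * N:
            s_plus = s_plus_next
            converged = True
            break
        s_plus = s_plus_next
    if not converged:
        raise ConvergenceError(
            f"pulse cycle did not reach a periodic attractor in {max_cycles} cycles"
        )
    t_eval = np.linspace(0.0, tau, n_quadrature)
    sol = flow(s_plus, t_eval=t_eval)
    s_bar = float(np.trapezoid(sol.y[0], sol.t) / tau) / N
    return shin0 - s_bar
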