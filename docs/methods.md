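# Methods

## The model

`strs` implements a behavioral-contagion model of norm violation in a
closed, egalitarian ("covenantal") community that polices itself through a
periodic assembly rather than through a dedicated enforcement class.  A
population of constant size N is partitioned into susceptibles S (open to
corruption), transgressors T (violating the shared code), and righteous R
(determinedly obeying it).  The flow S → T → R → S is an SIRS epidemic
structure in which infection is corruption by contact with transgressors,
recovery is repentance, and loss of immunity is lapse:

    dS/dt = alpha R - beta S T / N
    dT/dt = beta S T / N - gamma(t) T
    dR/dt = gamma(t) T - alpha R

All rates are per week.  Two dimensionless indices organise the behaviour:

* **Basic Sabbath Number** `shin_0 = gamma_bar / beta`, the reciprocal of
  the epidemiological basic reproduction number; it measures the resistance
  of a susceptible to corruption by a typical transgressor.
* **Cohesion factor** `gamma_bar / alpha`, the ratio of repentance to
  lapse; it controls how the non-susceptible population divides between
  transgressors and righteous at the endemic state (+inf when alpha = 0).

Three variants are provided:

1. **Unforced** — constant gamma.  Two equilibria: the transgressor-free
   state (N, 0, 0), stable iff shin_0 > 1, and the endemic state
   S*/N = gamma/beta, T*/N = (1 - gamma/beta)/(1 + gamma/alpha),
   R*/N = (1 - gamma/beta)/(1 + alpha/gamma), existing and stable iff
   shin_0 < 1.  They exchange stability in a transcritical bifurcation at
   shin_0 = 1, which `locate_transcritical` recovers numerically by
   bisection on the dominant Jacobian eigenvalue (to 1e-10 or better).
2. **Periodically forced** — gamma(t) is a mean plus harmonics
   (`RepentanceForcing`), the weekly assembly as a clock; the canonical
   example is gamma(t) = 1 + sin(2 pi t).  The Floquet multiplier of the
   linearised transgressor equation T' = (beta - gamma(t)) T over one
   period equals exp((beta - gamma_bar) * period): only the mean rate
   survives the integral, so the forced threshold coincides with the
   unforced one and is amplitude-independent.  `floquet_multiplier`
   computes the multiplier by direct integration precisely so this
   reduction is verified numerically rather than assumed.
3. **Impulsively pulsed** — the "direct route to righteousness": every tau
   weeks a proportion p of susceptibles moves instantaneously to R
   (a pulse-vaccination analogue).  Pulses are Dirac impulses implemented
   by stop-restart integration with bit-exact pulse arithmetic
   (S' = (1-p)S, R' = R + pS), never by smoothing the delta function.
   The extinction criterion compares shin_0 with the susceptible
   proportion averaged over one pulse cycle at the transgressor-free
   periodic attractor (`pulsed_threshold_margin`); with p = 0 that average
   is 1 and the unforced criterion is recovered.

The classical predator–prey model of criminals versus police (dx/dt =
ax - bxy, dy/dt = cxy - dy) is included as the stratified-society baseline;
its conserved first integral c x - d ln x + b y - a ln y doubles as a sharp
integrator-quality oracle.

## Parameters and defaults

| parameter | meaning | unit | default / convention |
|---|---|---|---|
| beta | contagiousness of transgression | 1/week | scenario-specific; 1.46 from the heroin-addiction calibration, ~1.5 for small congregations |
| gamma_bar | mean repentance rate | 1/week | 1 (one-week average transgressor lifetime, matching a weekly assembly); proportional to assembly frequency |
| alpha | lapse rate R → S | 1/week | scenario-specific; gamma/alpha is the cohesion factor |
| omega | forcing angular frequency | rad/week | 2 pi (one-week period) |
| p | pulse proportion | — | 0.5 in the pulsed scenarios |
| tau | pulse interval | weeks | 1 (weekly) or 2 (fortnightly); first pulse at t = tau |
| N | population size | persons | 100 for the wave panels, 1 for fraction-normalised pulsed runs |

The first pulse fires at t = tau, not t = 0, so a stated initial condition
is the pre-assembly state and the first visible drop occurs after one full
interval; `first_pulse_time` makes the other convention available.

## Numerical choices

* Integration uses `scipy.integrate.solve_ivp` with RK45 at
  rtol 1e-10 / atol 1e-12 on the reduced (S, T) system with
  R = total - S - T, which conserves the population total exactly by
  construction.  RK45 was chosen over the higher-order DOP853 because
  DOP853's dense-output interpolant can overshoot the invariant region
  (S > N by ~1e-3 N) when a trajectory is sampled on a fine grid across
  long, rapidly flattening decay segments; RK45's interpolant stays within
  ~1e-8 N of the region at these tolerances.
* Solver undershoot below zero smaller than 1e-9·N in magnitude is clamped
  to zero in outputs; anything larger raises an integration failure rather
  than being silently repaired.
* Forcing nonnegativity is certified by sampling 1000 equispaced points
  over one period at construction time; exact minimisation over arbitrary
  harmonic sets is unnecessary at the precision involved and sampling is
  robust.  For the sinusoidal kind, amplitude <= mean is required, which is
  sufficient.
* Fourier forcing takes the real part of mean + sum_n gamma_n e^{i n omega t};
  a pure sine of amplitude delta is the single harmonic gamma_1 = -i delta.
* Stability is classified on the reduced 2-D Jacobian; the 3-D system's
  structural zero eigenvalue (conservation) would otherwise obscure the
  verdict.  A zero real part is classified "neutral" — neither stable nor
  unstable — which is how alpha = 0 manifests at the transgressor-free
  state (cohesion reported as +inf).
* The pulse-cycle map in `pulsed_threshold_margin` is iterated at most 100
  cycles or until the post-pulse susceptible value changes by less than
  1e-10·N, whichever comes first; the cycle average is then a trapezoidal
  quadrature on 2001 points.  Slowly contracting schedules (contraction
  factor (1-p)e^{-alpha tau} near 1, e.g. the biannual-pulse regime) may
  need a larger `max_cycles`.
* Terminal averages (`periodic_steady_state_average`) are trapezoidal over
  the last n_periods × period, with the window's left endpoint linearly
  interpolated onto the grid.
* "Die-out" is operationalised as T < 1e-6·N sustained to the end of the
  horizon.  Default horizons: 300 weeks for the wave panels and the
  weekly/fortnightly pulsed runs, 50 pulse cycles for the biannual-pulse
  regime, 10 weeks for the heroin calibration.

## Scenario fixtures

The registry reproduces every published simulation.  The transgression-wave
panels are printed only as index pairs (Sabbath number 0.6 or 1.1, cohesion
0.4, N = 100, T0 = 5); absolute rates follow from the gamma = 1/week
convention, recorded in each fixture's provenance.  The heroin calibration
inserts S0 = 50, T0 = 1 against a contact divisor N = 50 exactly as
printed; the conserved total along that trajectory is therefore 51, and the
library treats conservation as constancy of S + T + R rather than equality
with N.  The biannual-pulse fixture uses the caption's parameter list
(p = 0.1, tau = 104, alpha = 0.00027, beta = 10, gamma = 1); because the
caption's prose contradicts both its own parameter list and the body text
on the qualitative outcome, the fixture asserts only boundedness, not
extinction.

The seeded random-scenario generator draws the Sabbath number and cohesion
factor uniformly from requested ranges at gamma_bar = 1, seeds a 5%
transgressor perturbation, and (optionally) draws a sinusoidal amplitude in
[0, gamma_bar] so forcing validity holds by construction.  It emulates the
parameter regimes of the published runs; it does not emulate demographic
turnover, stochastic contact structure, or measurement noise, so passing
property tests demonstrate correctness of the deterministic model and its
analysis, not fit to any behavioral dataset.

## Design notes and limitations

* The weekly-versus-fortnightly comparison (gamma_bar proportional to
  assembly frequency, alpha and beta fixed) claims the weekly endemic
  transgressor load is under half the fortnightly one.  Algebra on the
  closed form shows this holds iff shin_0(fortnightly) × (3 + 2
  gamma_f/alpha) > 1 — guaranteed whenever the weekly index is at least
  2/3, the near-threshold regime the comparison contemplates (communities
  "critically close" to threshold), but false for strongly sub-threshold
  communities.  Tests therefore quantify over weekly indices in
  [0.7, 0.99].
* Compartments are real-valued (continuum model); rounding to whole
  individuals happens only at reporting.
* No stochastic (agent-based or Gillespie) formulation, no age or stratum
  structure, no demography.  Chaos in the long-interval pulsed regime is
  exhibited (bounded, aperiodic trajectories) but not quantified — no
  Lyapunov exponents.
* Global stability is not proved; all stability statements are local
  (eigenvalue/Floquet) plus long-horizon simulation agreement.
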