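"""Equilibrium, stability, threshold, Floquet, and pulsed-criterion tests."""

import math

import numpy as np
import pytest

import strs
from strs import (
    BracketError,
    CompartmentState,
    InvalidParameterError,
    NoEndemicEquilibriumError,
    PulseSchedule,
    RepentanceForcing,
    STRSParams,
    bifurcation_curve,
    endemic_report,
    floquet_multiplier,
    integrate,
    locate_transcritical,
    pulsed_threshold_margin,
    sabbath_indices,
    strs_derivatives,
    transgressor_free_report,
)


class TestSabbathIndices:
    def test_hand_values(self):
        idx = sabbath_indices(STRSParams.with_constant_gamma(0.63, 1.5, 0.9))
        assert idx.basic_sabbath_number == pytest.approx(0.6)
        assert idx.cohesion_factor == pytest.approx(0.9 / 0.63)
        unit = sabbath_indices(STRSParams.with_constant_gamma(1.0, 1.0, 1.0))
        assert unit.basic_sabbath_number == 1.0

    def test_zero_lapse_gives_infinite_cohesion(self):
        idx = sabbath_indices(STRSParams.with_constant_gamma(0.0, 2.0, 1.0))
        assert math.isinf(idx.cohesion_factor)

    def test_doubling_mean_rate_doubles_index(self):
        """Halving the assembly interval doubles gamma_bar, hence the index."""
        weekly = sabbath_indices(STRSParams.with_constant_gamma(0.5, 1.2, 1.0))
        fortnightly = sabbath_indices(STRSParams.with_constant_gamma(0.5, 1.2, 0.5))
        assert weekly.basic_sabbath_number == 2 * fortnightly.basic_sabbath_number


class TestTransgressorFreeReport:
    def test_state_is_all_susceptible(self):
        report = transgressor_free_report(
            STRSParams.with_constant_gamma(0.63, 1.5, 0.9, N=7.0)
        )
        assert (report.state.S, report.state.T, report.state.R) == (7.0, 0.0, 0.0)

    def test_eigenvalues_above_threshold(self):
        # gamma=1, beta=10/11: eigenvalues -alpha = -5/2 and beta-gamma = -1/11
        report = transgressor_free_report(
            STRSParams.with_constant_gamma(2.5, 10.0 / 11.0, 1.0, N=100.0)
        )
        reals = sorted(ev.real for ev in report.eigenvalues)
        assert reals[0] == pytest.approx(-2.5, abs=1e-12)
        assert reals[1] == pytest.approx(-1.0 / 11.0, abs=1e-12)
        assert report.stable and report.classification == "stable"

    def test_unstable_below_threshold(self):
        report = transgressor_free_report(
            STRSParams.with_constant_gamma(0.63, 1.5, 0.9)
        )
        assert max(ev.real for ev in report.eigenvalues) == pytest.approx(0.6)
        assert not report.stable and report.classification == "unstable"

    def test_zero_lapse_is_neutral(self):
        report = transgressor_free_report(
            STRSParams.with_constant_gamma(0.0, 1.0, 2.0)
        )
        assert report.classification == "neutral"
        assert not report.stable


class TestEndemicReport:
    def test_closed_form_hand_values(self):
        # shin0 = 0.6, cohesion 0.4, N = 100 -> (60, 200/7, 80/7)
        report = endemic_report(
            STRSParams.with_constant_gamma(2.5, 5.0 / 3.0, 1.0, N=100.0)
        )
        assert report.state.S == pytest.approx(60.0)
        assert report.state.T == pytest.approx(200.0 / 7.0)
        assert report.state.R == pytest.approx(80.0 / 7.0)
        assert report.stable

    def test_threshold_boundary_coincides_with_transgressor_free(self):
        report = endemic_report(STRSParams.with_constant_gamma(0.5, 1.0, 1.0, N=50.0))
        assert report.state.T == pytest.approx(0.0, abs=1e-12)
        assert report.state.S == pytest.approx(50.0)

    def test_unit_cohesion_splits_non_susceptibles_evenly(self):
        report = endemic_report(STRSParams.with_constant_gamma(1.0, 2.0, 1.0, N=100.0))
        assert report.state.T == report.state.R

    def test_absent_above_threshold(self):
        with pytest.raises(NoEndemicEquilibriumError):
            endemic_report(STRSParams.with_constant_gamma(1.0, 1.0, 2.0))

    @pytest.mark.parametrize("name", ["fig2a_i", "fig4"])
    def test_reported_equilibria_are_fixed_points(self, name):
        params = strs.named_scenario(name).params
        for report in (transgressor_free_report(params), endemic_report(params)):
            derivs = strs_derivatives(report.state, params)
            assert max(abs(d) for d in derivs) < 1e-10


class TestTranscritical:
    def test_critical_index_is_unity(self):
        assert locate_transcritical(1.0, 0.5, (0.5, 2.0)) == pytest.approx(
            1.0, abs=1e-10
        )

    def test_threshold_independent_of_lapse_rate(self):
        assert locate_transcritical(0.9, 0.63, (0.45, 1.8)) == pytest.approx(
            1.0, abs=1e-10
        )

    def test_unbracketed_range_rejected(self):
        with pytest.raises(BracketError):
            locate_transcritical(1.0, 0.5, (1.5, 2.0))


class TestBifurcationCurve:
    def test_branches_and_continuity(self):
        grid = np.array([0.0, 0.5, 1.0 - 1e-12, 1.0, 1.1, 2.0])
        curve = bifurcation_curve(0.4, grid, N=100.0)
        assert curve[-2:] == pytest.approx(0.0)  # above threshold: T* = 0
        assert curve[1] == pytest.approx(100.0 * 0.5 / 1.4)
        assert curve[2] == pytest.approx(0.0, abs=1e-9)  # continuous at threshold
        # cohesion 0.4, shin0 = 0.6 reproduces the endemic hand value 200/7
        assert bifurcation_curve(0.4, np.array([0.6]), N=100.0)[0] == pytest.approx(
            200.0 / 7.0
        )

    def test_large_cohesion_flattens_endemic_branch(self):
        grid = np.linspace(0.0, 0.99, 50)
        strong = bifurcation_curve(1e6, grid, N=1.0)
        assert np.all(strong < 1e-6)
        assert np.all(bifurcation_curve(math.inf, grid, N=1.0) == 0.0)

    def test_monotone_in_cohesion_and_in_sabbath_number(self):
        grid = np.linspace(0.05, 0.95, 19)
        curves = [bifurcation_curve(c, grid, N=1.0) for c in (0.2, 1.0, 5.0)]
        # T* decreases with cohesion at fixed shin0 ...
        assert np.all(curves[0] > curves[1]) and np.all(curves[1] > curves[2])
        # ... and decreases with shin0 at fixed cohesion
        for curve in curves:
            assert np.all(np.diff(curve) < 0)


class TestFloquet:
    def test_threshold_multiplier_is_unity(self):
        forcing = RepentanceForcing(kind="sinusoidal", mean=1.0, amplitude=1.0)
        params = STRSParams(alpha=0.5, beta=1.0, forcing=forcing)
        assert floquet_multiplier(params) == pytest.approx(1.0, rel=1e-8)

    def test_stable_above_threshold_amplitude_independent(self):
        beta = 1.0
        for delta in (0.0, 0.3, 1.1):
            forcing = RepentanceForcing(kind="sinusoidal", mean=1.1 * beta,
                                        amplitude=delta)
            params = STRSParams(alpha=0.5, beta=beta, forcing=forcing)
            assert floquet_multiplier(params) == pytest.approx(
                math.exp(-0.1 * beta), rel=1e-8
            )

    def test_matches_exponential_for_arbitrary_harmonics(self):
        """Monodromy oracle: only gamma_bar survives one full period, so the
        multiplier equals exp((beta - gamma_bar)*period) for any harmonic mix."""
        forcing = RepentanceForcing(
            kind="fourier", mean=1.2, harmonics=(-0.4j, 0.3, 0.1j)
        )
        params = STRSParams(alpha=0.7, beta=1.5, forcing=forcing)
        expected = math.exp((1.5 - 1.2) * forcing.period)
        assert floquet_multiplier(params) == pytest.approx(expected, rel=1e-8)


class TestPulsedThresholdMargin:
    def test_no_pulse_reduces_to_unforced_criterion(self):
        params = STRSParams.with_constant_gamma(0.63, 1.5, 0.9, N=1.0)
        margin = pulsed_threshold_margin(params, PulseSchedule(p=0.0, tau=1.0))
        assert margin == pytest.approx(0.6 - 1.0, abs=1e-8)

    def test_weekly_pulses_predict_extinction(self):
        sc = strs.named_scenario("fig5")
        assert pulsed_threshold_margin(sc.params, sc.pulses) > 0

    def test_fortnightly_pulses_predict_persistence(self):
        sc = strs.named_scenario("fig4")
        assert pulsed_threshold_margin(sc.params, sc.pulses) < 0

    def test_periodic_forcing_rejected(self):
        forcing = RepentanceForcing(kind="sinusoidal", mean=1.0, amplitude=0.5)
        params = STRSParams(alpha=0.5, beta=1.0, forcing=forcing)
        with pytest.raises(InvalidParameterError):
            pulsed_threshold_margin(params, PulseSchedule(p=0.5, tau=1.0))


class TestStabilityExchange:
    @pytest.mark.parametrize("seed", range(8))
    def test_exchange_at_unit_sabbath_number(self, seed):
        """Transgressor-free stable iff shin0 > 1; endemic stable iff shin0 < 1."""
        sc = strs.random_scenario(seed, sabbath_range=(0.4, 1.6))
        params = sc.params
        shin0 = sabbath_indices(params).basic_sabbath_number
        tf = transgressor_free_report(params)
        assert tf.stable == (shin0 > 1.0)
        if shin0 < 1.0:
            assert endemic_report(params).stable

    @pytest.mark.parametrize("seed", [1, 3])
    def test_long_run_simulation_agrees_with_analysis(self, seed):
        """Long-horizon integration lands on whichever equilibrium is stable."""
        sc = strs.random_scenario(seed, sabbath_range=(0.4, 1.6))
        params = sc.params
        traj = integrate(params, sc.init, (0.0, 400.0))
        shin0 = sabbath_indices(params).basic_sabbath_number
        target = (
            endemic_report(params).state
            if shin0 < 1.0
            else CompartmentState(S=params.N, T=0.0, R=0.0)
        )
        final = traj.final_state
        assert abs(final.S - target.S) < 1e-4 * params.N
        assert abs(final.T - target.T) < 1e-4 * params.N

    @pytest.mark.parametrize("seed", range(6))
    def test_weekly_beats_fortnightly_by_more_than_half(self, seed):
        """With gamma_bar proportional to assembly frequency and the weekly
        index in the near-threshold regime (>= 2/3), the weekly endemic
        transgressor load is below half the fortnightly one."""
        rng = np.random.default_rng(seed)
        shin_weekly = rng.uniform(0.7, 0.99)
        beta = 1.0 / shin_weekly  # weekly gamma_bar = 1
        alpha = rng.uniform(0.2, 5.0)
        weekly = endemic_report(
            STRSParams.with_constant_gamma(alpha, beta, 1.0, N=100.0)
        ).state.T
        fortnightly = endemic_report(
            STRSParams.with_constant_gamma(alpha, beta, 0.5, N=100.0)
        ).state.T
        assert weekly < 0.5 * fortnightly
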