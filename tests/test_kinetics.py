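"""Tight-binding kinetics: model, fitting, correction, titration, reversibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxkit.kinetics import (
    AssayCondition,
    InhibitionCurve,
    KineticsError,
    NoInhibitionError,
    ReversibilityVerdict,
    TitrationSeries,
    assess_reversibility,
    classify_tight_binding,
    correct_ki,
    equilibrium_fraction_bisection,
    fit_ki_app,
    morrison_fraction,
    titrate_active_concentration,
)
from toxkit.synth import gen_morrison_curve, gen_titration

nM = 1e-9


class TestMorrisonFraction:
    def test_no_inhibitor_gives_full_activity(self):
        assert morrison_fraction(27 * nM, 0.0, 5.4 * nM) == 1.0

    def test_stoichiometric_limit_is_one_minus_ratio(self):
        # As Ki_app -> 0 binding is stoichiometric: vi/v0 -> 1 - I0/E0.
        assert morrison_fraction(10 * nM, 4 * nM, 1e-20) == pytest.approx(0.6, abs=1e-9)

    def test_agrees_with_mass_balance_bisection(self):
        got = morrison_fraction(27 * nM, 27 * nM, 5.4 * nM)
        want = equilibrium_fraction_bisection(27 * nM, 27 * nM, 5.4 * nM)
        assert got == pytest.approx(want, rel=1e-10)

    @pytest.mark.parametrize("bad", [(-1e-9, 1e-9, 1e-9), (1e-9, -1e-9, 1e-9),
                                     (1e-9, 1e-9, 0.0), (float("nan"), 1e-9, 1e-9)])
    def test_rejects_invalid_inputs(self, bad):
        with pytest.raises(KineticsError):
            morrison_fraction(*bad)

    @given(
        e0=st.floats(1e-10, 1e-4), ki=st.floats(1e-10, 1e-4),
        i_lo=st.floats(0, 1e-4), step=st.floats(1e-12, 1e-4),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_non_increasing_in_inhibitor(self, e0, ki, i_lo, step):
        assert (morrison_fraction(e0, i_lo + step, ki)
                <= morrison_fraction(e0, i_lo, ki) + 1e-12)

    def test_bounded_in_unit_interval_on_random_grid(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            e0, i0, ki = 10 ** rng.uniform(-10, -4, 3)
            f = morrison_fraction(e0, i0, ki)
            assert 0.0 <= f <= 1.0


class TestFitKiApp:
    @pytest.mark.parametrize("ratio", [0.01, 0.1, 1.0, 10.0, 100.0])
    def test_noise_free_round_trip_across_ki_regimes(self, ratio):
        """Fitting model-generated data recovers Ki_app over 4 decades of
        Ki_app/E0."""
        e0 = 100 * nM
        ki_true = ratio * e0
        curve = gen_morrison_curve(E0=e0, Ki_app=ki_true, n_points=12,
                                   I_max_over_E0=5 + 10 * ratio)
        fit = fit_ki_app(curve)
        assert fit.converged
        assert fit.Ki_app == pytest.approx(ki_true, rel=1e-6)

    def test_flat_curve_raises_no_inhibition(self):
        cond = AssayCondition(enzyme_id="factor-Xa-like", E0=100 * nM)
        curve = InhibitionCurve(
            condition=cond,
            I_grid=tuple(np.linspace(0, 5e-7, 8)),
            fractional_activity=(1.0,) * 8,
        )
        with pytest.raises(NoInhibitionError):
            fit_ki_app(curve)

    def test_activity_units_enzyme_cannot_be_fit(self):
        cond = AssayCondition(enzyme_id="thrombin", E0=1.0,
                              activity_units_only=True)
        curve = InhibitionCurve(
            condition=cond,
            I_grid=tuple(np.linspace(0, 5e-7, 8)),
            fractional_activity=tuple(np.linspace(1.0, 0.2, 8)),
        )
        with pytest.raises(KineticsError, match="activity units"):
            fit_ki_app(curve)

    def test_too_few_points_rejected(self):
        cond = AssayCondition(enzyme_id="trypsin", E0=100 * nM)
        curve = InhibitionCurve(
            condition=cond, I_grid=(0.0, 1e-8, 2e-8, 4e-8),
            fractional_activity=(1.0, 0.8, 0.6, 0.4),
        )
        with pytest.raises(KineticsError, match=">= 5"):
            fit_ki_app(curve)

    def test_noisy_recovery_median_within_ten_percent(self):
        """At 2% multiplicative noise the median recovered Ki_app over many
        seeded replicates stays within 10% of truth."""
        ki_true = 10 * nM
        estimates = []
        for seed in range(200):
            curve = gen_morrison_curve(E0=100 * nM, Ki_app=ki_true,
                                       n_points=12, noise_sd=0.02, seed=seed)
            estimates.append(fit_ki_app(curve).Ki_app)
        median = float(np.median(estimates))
        assert abs(median - ki_true) / ki_true < 0.10


class TestCorrectKi:
    def test_s0_equal_km_halves_ki_app(self):
        assert correct_ki(5.4 * nM, 1e-3, 1e-3) == pytest.approx(2.7 * nM)
        assert correct_ki(29.2 * nM, 5e-4, 5e-4) == pytest.approx(14.6 * nM)

    def test_zero_substrate_leaves_ki_unchanged(self):
        assert correct_ki(3.3 * nM, 0.0, None) == 3.3 * nM

    def test_missing_km_is_an_error_not_a_passthrough(self):
        with pytest.raises(KineticsError, match="correction unavailable"):
            correct_ki(5.4 * nM, 1e-3, None)

    @given(ki=st.floats(1e-12, 1e-6), s_over_km=st.floats(0.01, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_exact_round_trip_and_contraction(self, ki, s_over_km):
        km = 1e-3
        s0 = s_over_km * km
        ki_app = ki * (1.0 + s_over_km)
        assert correct_ki(ki_app, s0, km) == pytest.approx(ki, rel=1e-12)
        assert correct_ki(ki_app, s0, km) <= ki_app

    def test_strictly_decreasing_in_substrate_load(self):
        vals = [correct_ki(1e-8, s, 1e-3) for s in (1e-4, 1e-3, 1e-2)]
        assert vals[0] > vals[1] > vals[2]


class TestClassifyTightBinding:
    @pytest.mark.parametrize("ki,expected", [
        (2.7e-9, True),   # trypsin-range constant
        (1.0e-7, True),   # boundary inclusive
        (5.0e-7, False),
    ])
    def test_threshold(self, ki, expected):
        assert classify_tight_binding(ki) is expected


class TestTitration:
    def test_noise_free_round_trip_recovers_active_concentration(self):
        series = gen_titration(active_conc=100 * nM, E_total=100 * nM,
                               n_points=12)
        result = titrate_active_concentration(series)
        assert result.active_concentration == pytest.approx(100 * nM, rel=5e-3)
        assert not result.warnings

    def test_low_enzyme_excess_attaches_validity_warning(self):
        series = gen_titration(active_conc=100 * nM, E_total=100 * nM,
                               n_points=12, E0_over_Ki=10)
        result = titrate_active_concentration(series)
        assert any("E0/Ki" in w for w in result.warnings)

    def test_flat_series_has_no_signal(self):
        series = TitrationSeries(
            E_total=1e-7, inhibitor_amounts=tuple(np.linspace(0, 2e-7, 8)),
            fractional_activity=(1.0,) * 8, E0_over_Ki=1000,
        )
        with pytest.raises(KineticsError, match="no titration signal"):
            titrate_active_concentration(series)

    def test_sparse_linear_region_underdetermined(self):
        series = TitrationSeries(
            E_total=1e-7,
            inhibitor_amounts=(0.0, 5e-8, 1.9e-7, 2e-7),
            fractional_activity=(1.0, 0.5, 0.02, 0.0),
            E0_over_Ki=1000,
        )
        with pytest.raises(KineticsError, match="underdetermined"):
            titrate_active_concentration(series)


class TestReversibility:
    def test_substrate_relief_and_time_stability_mean_reversible(self):
        # Activity rising with substrate at 0.5/1/2 KM, flat over time.
        out = assess_reversibility(
            S0_levels=(0.5, 1.0, 2.0),
            vi_over_v0_at_levels=(0.55, 0.63, 0.72),
            preincubation_minutes=(1, 5, 10, 20),
            vi_over_v0_at_times=(0.63, 0.62, 0.63, 0.64),
        )
        assert out.verdict is ReversibilityVerdict.reversible_substrate_competitive

    def test_flat_substrate_response_is_inconsistent(self):
        out = assess_reversibility(
            S0_levels=(0.5, 1.0, 2.0),
            vi_over_v0_at_levels=(0.60, 0.60, 0.61),
            preincubation_minutes=(1, 20),
            vi_over_v0_at_times=(0.60, 0.60),
        )
        assert out.verdict is ReversibilityVerdict.inconsistent

    def test_falling_time_course_means_equilibrium_not_reached(self):
        out = assess_reversibility(
            S0_levels=(0.5, 1.0, 2.0),
            vi_over_v0_at_levels=(0.55, 0.63, 0.72),
            preincubation_minutes=(1, 5, 10, 20),
            vi_over_v0_at_times=(0.80, 0.70, 0.60, 0.50),
        )
        assert out.verdict is ReversibilityVerdict.equilibrium_not_reached

    def test_mismatched_conditions_rejected(self):
        with pytest.raises(KineticsError, match="identical"):
            assess_reversibility(
                S0_levels=(0.5, 1.0, 2.0),
                vi_over_v0_at_levels=(0.55, 0.63, 0.72),
                preincubation_minutes=(1, 20),
                vi_over_v0_at_times=(0.6, 0.6),
                E0_at_levels=(1e-7, 1e-7, 2e-7),
            )
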