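"""First-order rate fitting, Arrhenius analysis and shelf-life extrapolation."""

import math

import numpy as np
import pytest

import ribotrace as rt
from ribotrace.errors import FitError
from ribotrace.kinetics import StabilitySeries, celsius_to_kelvin


def _series(T, t, integ):
    return StabilitySeries(T, np.asarray(t, float), np.asarray(integ, float))


class TestFitFirstOrder:
    def test_constant_integrity_gives_zero_rate(self):
        fit = rt.fit_first_order(_series(4.0, [0, 10, 30, 60], [80, 80, 80, 80]),
                                 mode="full-curve")
        assert fit.k_per_day == 0.0

    def test_exact_exponential_recovered_to_machine_precision(self):
        k = 0.02
        t = np.array([0.0, 10.0, 30.0, 60.0])
        integ = 80.0 * np.exp(-k * t)
        fit = rt.fit_first_order(_series(25.0, t, integ), mode="full-curve")
        assert fit.k_per_day == pytest.approx(k, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_ten_percent_drop_over_90_days(self):
        # integrity 80 -> 72 (factor 0.9) over 90 days
        fit = rt.fit_first_order(_series(4.0, [0.0, 90.0], [80.0, 72.0]),
                                 mode="initial-rate")
        assert fit.k_per_day == pytest.approx(-math.log(0.9) / 90.0, rel=1e-12)
        assert fit.k_per_day == pytest.approx(1.171e-3, rel=1e-3)

    def test_zero_integrity_points_excluded_and_counted(self):
        t = [0.0, 10.0, 20.0, 40.0, 60.0]
        integ = [80.0, 40.0, 20.0, 0.0, 0.0]
        fit = rt.fit_first_order(_series(60.0, t, integ), mode="full-curve")
        assert fit.n_excluded == 2
        assert fit.n_used == 3

    def test_initial_rate_uses_first_three_points(self):
        k_early = 0.05
        t = np.array([0.0, 2.0, 4.0, 30.0, 60.0])
        integ = 80.0 * np.exp(-k_early * t)
        integ[3:] = [60.0, 59.0]  # late-time flattening
        fit = rt.fit_first_order(_series(37.0, t, integ), mode="initial-rate")
        assert fit.k_per_day == pytest.approx(k_early, rel=1e-9)
        assert fit.n_used == 3

    def test_negative_rate_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            fit = rt.fit_first_order(_series(4.0, [0, 30, 60], [80, 81, 82]),
                                     mode="full-curve")
        assert fit.k_per_day == 0.0

    def test_insufficient_points_raise(self):
        with pytest.raises(FitError):
            rt.fit_first_order(_series(60.0, [0.0, 5.0], [80.0, 0.0]))


class TestFitArrhenius:
    def test_equal_rates_give_zero_activation_energy(self):
        fit = rt.fit_arrhenius([(4.0, 0.01), (25.0, 0.01), (45.0, 0.01)])
        assert fit.Ea_kJ_mol == pytest.approx(0.0, abs=1e-12)

    def test_two_point_exact_recovery_of_74_8(self):
        truth = rt.KineticTruth(Ea=74.8, lnA=25.712)
        pairs = [(T, rt.arrhenius_rate(truth, celsius_to_kelvin(T)))
                 for T in (4.0, 45.0)]
        fit = rt.fit_arrhenius(pairs)
        assert fit.Ea_kJ_mol == pytest.approx(74.8, rel=1e-12)
        assert fit.lnA == pytest.approx(25.712, rel=1e-12)

    def test_noisy_monte_carlo_recovery_and_coverage(self):
        truth = rt.KineticTruth()
        temps = np.array([-20.0, 4.0, 25.0, 37.0, 45.0, 60.0])
        k_true = np.array([rt.arrhenius_rate(truth, celsius_to_kelvin(T))
                           for T in temps])
        rng = np.random.default_rng(2024)
        estimates, covered = [], 0
        for _ in range(100):
            k_noisy = k_true * np.exp(rng.normal(0.0, 0.05, temps.size))
            fit = rt.fit_arrhenius(list(zip(temps, k_noisy)), k_se=0.05 * k_noisy)
            estimates.append(fit.Ea_kJ_mol)
            covered += abs(fit.Ea_kJ_mol - truth.Ea) <= 2.0 * fit.Ea_se
        assert abs(np.mean(estimates) - truth.Ea) / truth.Ea < 0.02
        assert covered >= 90

    def test_zero_rates_excluded_and_reported(self):
        fit = rt.fit_arrhenius([(-20.0, 0.0), (25.0, 0.01), (45.0, 0.08)])
        assert fit.excluded_temperatures == [-20.0]
        assert fit.n_used == 2

    def test_all_zero_rates_error(self):
        with pytest.raises(FitError, match="no measurable degradation"):
            rt.fit_arrhenius([(4.0, 0.0), (25.0, 0.0)])

    def test_larger_activation_energy_gives_steeper_slope(self):
        temps = (4.0, 25.0, 45.0)
        slopes = []
        for Ea in (40.0, 74.8, 120.0):
            truth = rt.KineticTruth(Ea=Ea, lnA=25.0)
            pairs = [(T, rt.arrhenius_rate(truth, celsius_to_kelvin(T)))
                     for T in temps]
            fit = rt.fit_arrhenius(pairs)
            slopes.append(fit.Ea_kJ_mol)
        assert slopes[0] < slopes[1] < slopes[2]


class TestPredictTimeToLoss:
    def test_zero_order_360_day_extrapolation(self):
        days = rt.predict_time_to_loss(
            0.5, model="zero-order",
            rate_points_per_day=10.0 / 90.0, start_integrity=80.0,
        )
        assert days == pytest.approx(360.0)

    def test_first_order_half_life(self):
        days = rt.predict_time_to_loss(0.5, model="first-order", k_per_day=0.00117)
        assert days == pytest.approx(math.log(2) / 0.00117, rel=1e-12)
        assert days == pytest.approx(592.0, abs=1.0)

    def test_both_models_vanish_as_loss_goes_to_zero(self):
        for model, kwargs in (
            ("first-order", dict(k_per_day=0.01)),
            ("zero-order", dict(rate_points_per_day=0.1, start_integrity=80.0)),
        ):
            assert rt.predict_time_to_loss(1e-9, model=model, **kwargs) < 1e-5

    def test_models_disagree_on_the_same_observation(self):
        # 10 points lost from 80% over 90 days, extrapolated to 50% loss
        zero = rt.predict_time_to_loss(0.5, model="zero-order",
                                       rate_points_per_day=10.0 / 90.0,
                                       start_integrity=80.0)
        first = rt.predict_time_to_loss(0.5, model="first-order",
                                        k_per_day=-math.log(0.9) / 90.0)
        assert zero == pytest.approx(360.0)
        assert first == pytest.approx(592.0, abs=1.0)
        assert first != zero

    def test_zero_rate_is_infinite_with_warning(self):
        with pytest.warns(UserWarning):
            assert rt.predict_time_to_loss(0.5, k_per_day=0.0) == math.inf


class TestParameterRecoveryPipeline:
    def test_noiseless_study_recovers_truth_exactly(self):
        truth = rt.KineticTruth()
        study = rt.simulate_stability_study(truth)
        model = rt.DegradationStudy(
            study.truth.rename(columns={"integrity_pct": "integrity"})
        )
        res = model.fit(mode="full-curve", weighted_arrhenius=False)
        for _, row in res.rate_table.iterrows():
            k_true = rt.arrhenius_rate(truth, celsius_to_kelvin(row.temp_C))
            assert row.k_per_day == pytest.approx(k_true, rel=1e-9)
        assert res.arrhenius.Ea_kJ_mol == pytest.approx(truth.Ea, rel=1e-6)
        assert res.arrhenius.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_full_trace_pipeline_recovers_activation_energy(self, calibration):
        # traces with default detector noise, integrated then fitted
        from conftest import analyze_trace

        study = rt.simulate_stability_study(
            rt.KineticTruth(), noise=rt.NoiseModel(), seed=5
        )
        rows = []
        for tr in study.traces:
            res = analyze_trace(tr, calibration)
            rows.append({"temp_C": tr.meta.temp_C, "time_days": tr.meta.time_days,
                         "integrity": res.pct_main})
        import pandas as pd

        fit = rt.DegradationStudy(pd.DataFrame(rows)).fit(mode="full-curve")
        assert fit.arrhenius.Ea_kJ_mol == pytest.approx(74.8, rel=0.10)

    def test_summary_reports_parameters(self):
        study = rt.simulate_stability_study(rt.KineticTruth())
        model = rt.DegradationStudy(
            study.truth.rename(columns={"integrity_pct": "integrity"})
        )
        text = model.fit(mode="full-curve", weighted_arrhenius=False).summary()
        assert "Ea" in text and "kJ/mol" in text

    def test_arrhenius_table_columns(self):
        study = rt.simulate_stability_study(rt.KineticTruth())
        model = rt.DegradationStudy(
            study.truth.rename(columns={"integrity_pct": "integrity"})
        )
        tab = model.fit(mode="full-curve", weighted_arrhenius=False).arrhenius_table()
        assert set(tab.columns) == {"temp_C", "inv_T_K", "ln_k"}
        assert np.all(np.diff(tab.sort_values("temp_C").inv_T_K) < 0)
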