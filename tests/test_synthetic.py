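"""Generator-level checks: migration model, Arrhenius rates, trace structure,
stability-study bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import trapezoid

import ribotrace as rt
from ribotrace.synthetic import (
    GAS_CONSTANT,
    brij_area_factor,
    scenario_component_areas,
)


class TestSizeToTime:
    @pytest.mark.parametrize(
        "size, expected",
        [
            (2000.0, 49.0),                          # main-peak anchor
            (4000.0, 49.0 + 23.3 * np.log10(2.0)),   # HMW anchor ~56.0 s
            (200.0, 49.0 + 23.3 * np.log10(0.1)),    # smallest ladder rung, 25.7 s
        ],
    )
    def test_default_anchors(self, migration, size, expected):
        assert rt.size_to_time(migration, size) == pytest.approx(expected, abs=1e-9)

    def test_reference_size_maps_to_reference_time_for_any_slope(self):
        for slope in (5.0, 23.3, 80.0):
            m = rt.MigrationModel(slope=slope)
            assert rt.size_to_time(m, m.s_ref) == pytest.approx(m.t_ref)

    def test_out_of_range_size_rejected(self, migration):
        with pytest.raises(ValueError):
            rt.size_to_time(migration, 10.0)
        with pytest.raises(ValueError):
            rt.size_to_time(migration, 7000.0)

    @given(st.floats(min_value=50.0, max_value=5999.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_size(self, size):
        m = rt.MigrationModel()
        assert rt.size_to_time(m, size * 1.0001) > rt.size_to_time(m, size)


class TestArrheniusRate:
    def test_zero_activation_energy_gives_flat_rate(self):
        truth = rt.KineticTruth(Ea=0.0, lnA=-2.0)
        rates = [rt.arrhenius_rate(truth, T) for T in (253.15, 298.15, 333.15)]
        assert rates == pytest.approx([np.exp(-2.0)] * 3)

    def test_rate_ratio_between_45C_and_60C(self):
        truth = rt.KineticTruth(Ea=74.8, lnA=25.0)
        ratio = rt.arrhenius_rate(truth, 333.15) / rt.arrhenius_rate(truth, 318.15)
        expected = np.exp((74.8e3 / GAS_CONSTANT) * (1 / 318.15 - 1 / 333.15))
        assert ratio == pytest.approx(expected, rel=1e-12)
        assert ratio == pytest.approx(3.57, abs=0.01)

    def test_log_additivity_of_prefactor(self):
        a, b = 20.0, 1.7
        k1 = rt.arrhenius_rate(rt.KineticTruth(Ea=74.8, lnA=a), 300.0)
        k2 = rt.arrhenius_rate(rt.KineticTruth(Ea=74.8, lnA=a + b), 300.0)
        assert k2 == pytest.approx(k1 * np.exp(b), rel=1e-12)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            rt.arrhenius_rate(rt.KineticTruth(), 0.0)


class TestGenerateTrace:
    def test_pure_intact_sample_has_exactly_marker_and_main(self, calibration):
        scen = rt.SampleScenario(intact_fraction=1.0)
        tr = rt.generate_trace(scen)
        bl = rt.estimate_baseline(tr)
        peaks = rt.detect_peaks(tr, bl)
        assert len(peaks) == 2
        assert peaks[0].apex_time == pytest.approx(19.0, abs=0.05)
        assert peaks[1].apex_time == pytest.approx(49.0, abs=0.05)
        # fragment region is empty
        res = rt.integrate_regions(tr, bl, calibration, 2000.0)
        assert res.pct_fragments == pytest.approx(0.0, abs=1e-6)

    def test_heating_folds_hmw_into_main_conserving_area(self):
        base = dict(intact_fraction=0.7, hmw_fraction=0.2, formamide_pct=30.0)
        unheated = rt.generate_trace(rt.SampleScenario(heated=False, **base))
        heated = rt.generate_trace(rt.SampleScenario(heated=True, **base))
        t = unheated.time
        hmw_window = (t > 54.0) & (t < 58.5)
        hmw_area_unheated = trapezoid(unheated.signal[hmw_window], t[hmw_window])
        hmw_area_heated = trapezoid(heated.signal[hmw_window], t[hmw_window])
        assert hmw_area_unheated > 10 * max(hmw_area_heated, 1e-12)
        total_u = trapezoid(unheated.signal[t > 21], t[t > 21])
        total_h = trapezoid(heated.signal[t > 21], t[t > 21])
        assert total_h == pytest.approx(total_u, rel=0.01)

    def test_high_formamide_removes_hmw_even_without_heat(self):
        scen = rt.SampleScenario(intact_fraction=0.7, hmw_fraction=0.2,
                                 formamide_pct=85.0, heated=False)
        assert scenario_component_areas(scen)["hmw"] == 0.0

    def test_total_area_proportional_to_concentration(self):
        areas = []
        for conc in (5.0, 10.0):
            tr = rt.generate_trace(rt.SampleScenario(concentration=conc))
            mask = tr.time > 21.0  # exclude marker
            areas.append(trapezoid(tr.signal[mask], tr.time[mask]))
        assert areas[1] / areas[0] == pytest.approx(2.0, rel=1e-3)

    def test_brij_suppresses_area_but_not_purity(self, calibration):
        results = []
        for brij in (1.25, 10.0, 15.0):
            tr = rt.generate_trace(rt.SampleScenario(brij_pct=brij))
            res = rt.integrate_regions(tr, rt.estimate_baseline(tr), calibration, 2000.0)
            results.append((brij, res))
        totals = [r.total_area for _, r in results]
        assert totals[0] > totals[1] > totals[2]
        purities = [r.pct_main for _, r in results]
        assert max(purities) - min(purities) < 0.1
        assert brij_area_factor(10.0) == pytest.approx(1.0)
        assert brij_area_factor(15.0) == pytest.approx(0.8)
        assert brij_area_factor(1.25) == pytest.approx(1.35)

    def test_seed_determinism_bit_identical(self):
        noise = rt.NoiseModel(seed=42)
        tr1 = rt.generate_trace(rt.SampleScenario(), noise=noise)
        tr2 = rt.generate_trace(rt.SampleScenario(), noise=noise)
        assert np.array_equal(tr1.signal, tr2.signal)
        tr3 = rt.generate_trace(rt.SampleScenario(), noise=rt.NoiseModel(seed=43))
        assert not np.array_equal(tr1.signal, tr3.signal)

    def test_area_bookkeeping_matches_trapezoid_oracle(self):
        scen = rt.SampleScenario(intact_fraction=0.6, hmw_fraction=0.15,
                                 formamide_pct=30.0, heated=False)
        tr = rt.generate_trace(scen)
        intended = scenario_component_areas(scen)
        t, s = tr.time, tr.signal
        nonmarker = t > 21.0
        total = trapezoid(s[nonmarker], t[nonmarker])
        assert total == pytest.approx(intended["total"], rel=0.01)


class TestStabilityStudy:
    def test_time_zero_integrity_equals_start(self):
        study = rt.simulate_stability_study(rt.KineticTruth(), start_integrity=80.0)
        t0 = study.truth[study.truth.time_days == 0]
        assert np.allclose(t0.integrity_pct, 80.0)

    def test_integrity_non_increasing_in_temperature_at_fixed_time(self):
        study = rt.simulate_stability_study(rt.KineticTruth())
        at_30d = study.truth[study.truth.time_days == 30].sort_values("temp_C")
        vals = at_30d.integrity_pct.to_numpy()
        assert np.all(np.diff(vals) <= 0)

    def test_closed_form_decay_fraction(self):
        # k = 0.01/day for 90 days leaves e^-0.9 of the start
        truth = rt.KineticTruth(Ea=0.0, lnA=float(np.log(0.01)))
        study = rt.simulate_stability_study(
            truth, start_integrity=80.0, temperatures=[25.0], timepoints=[0.0, 90.0]
        )
        end = study.truth[study.truth.time_days == 90].integrity_pct.iloc[0]
        assert end == pytest.approx(80.0 * np.exp(-0.9), rel=1e-12)

    def test_ground_truth_strictly_decreasing_for_positive_rate(self):
        study = rt.simulate_stability_study(rt.KineticTruth())
        for _, grp in study.truth.groupby("temp_C"):
            vals = grp.sort_values("time_days").integrity_pct.to_numpy()
            assert np.all(np.diff(vals) < 0)

    def test_total_area_conserved_across_conditions(self):
        study = rt.simulate_stability_study(rt.KineticTruth())
        totals = []
        for tr in study.traces:
            mask = tr.time > 21.0
            totals.append(trapezoid(tr.signal[mask], tr.time[mask]))
        totals = np.array(totals)
        assert (totals.max() - totals.min()) / totals.mean() < 0.005

    def test_rejects_missing_time_zero_and_empty_lists(self):
        with pytest.raises(rt.RibotraceError):
            rt.simulate_stability_study(rt.KineticTruth(), timepoints=[4.0, 90.0])
        with pytest.raises(rt.RibotraceError):
            rt.simulate_stability_study(rt.KineticTruth(), temperatures=[])


class TestValidation:
    def test_scenario_fraction_bounds(self):
        with pytest.raises(ValueError):
            rt.SampleScenario(intact_fraction=0.8, hmw_fraction=0.3)
        with pytest.raises(ValueError):
            rt.SampleScenario(concentration=-1.0)

    def test_ladder_sizes_must_increase(self):
        with pytest.raises(ValueError):
            rt.LadderSpec(transcript_sizes=(500.0, 200.0))

    def test_migration_slope_must_be_positive(self):
        with pytest.raises(ValueError):
            rt.MigrationModel(slope=-1.0)
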