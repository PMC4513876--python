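"""Generator contracts: forward models, laws, determinism, validation."""

import numpy as np
import pytest

from phagetrans import (
    average_scans,
    fit_dna_peak,
    get_preset,
    hexagonal_q0,
    integrate_injections,
    make_ejection_events,
    make_saxs_profile,
    make_temperature_series,
    make_thermogram,
    sphere_form_factor,
    subtract_background,
    truncate_window,
)
from phagetrans.presets import ConditionPreset


class TestPresets:
    def test_transition_presets_match_measured_break_temperatures(self):
        expected = {"WT_Mg10": 33.0, "WT_Mg5": 22.0, "WT_Mg20": 37.0,
                    "WT_Mg50": 35.0, "L78_Mg10_EDTA": 36.0}
        for name, t_star in expected.items():
            assert get_preset(name).t_star_C == t_star
        for name in ("L78_Mg10", "L94_Mg10", "WT_Mg10_spermine"):
            assert get_preset(name).t_star_C is None

    def test_jump_is_the_measured_transition_enthalpy(self):
        from phagetrans import joules_to_kT

        wt = get_preset("WT_Mg10")
        assert joules_to_kT(wt.dH_jump_J, 33.0) == pytest.approx(1.8e4,
                                                                 rel=1e-3)

    def test_invalid_presets_rejected(self):
        with pytest.raises(ValueError, match="area_drop_frac"):
            ConditionPreset(name="bad", spacing_A=29.0, area_drop_frac=1.5)
        with pytest.raises(ValueError, match="strictly inside"):
            ConditionPreset(name="bad", spacing_A=29.0, t_star_C=100.0)
        with pytest.raises(KeyError, match="unknown preset"):
            get_preset("WT_Mg11")


class TestSaxsGenerator:
    def test_sphere_form_factor_is_unity_at_zero(self):
        assert sphere_form_factor(0.0) == pytest.approx(1.0)
        assert sphere_form_factor(1e-6) == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_peak_center_matches_hexagonal_law(self, l78_noiseless,
                                                         capsid):
        """78%-length preset (d = 29.6 A): fitted center 0.2451 1/A."""
        scan = make_saxs_profile(l78_noiseless, capsid, T=25.0, n_scans=1,
                                 seed=0)[0]
        buf = make_saxs_profile(l78_noiseless, capsid, T=25.0, n_scans=1,
                                seed=0, kind="buffer")[0]
        fit = fit_dna_peak(truncate_window(subtract_background(scan, buf)))
        assert fit.q0 == pytest.approx(0.2451, abs=2e-4)
        assert fit.q0 == pytest.approx(hexagonal_q0(29.6), rel=1e-3)

    def test_area_ratio_across_transition(self, wt_noiseless, capsid):
        """Noiseless WT at 34 vs 32 C: 0.7 of the linear trend."""
        areas = {}
        for T in (32.0, 34.0):
            scan = make_saxs_profile(wt_noiseless, capsid, T=T, n_scans=1,
                                     seed=0)[0]
            buf = make_saxs_profile(wt_noiseless, capsid, T=T, n_scans=1,
                                    seed=0, kind="buffer")[0]
            areas[T] = fit_dna_peak(
                truncate_window(subtract_background(scan, buf))
            ).A0
        trend = (1 - wt_noiseless.area_slope_per_C * 14.0) / (
            1 - wt_noiseless.area_slope_per_C * 12.0
        )
        assert areas[34.0] / areas[32.0] == pytest.approx(0.7 * trend,
                                                          rel=1e-3)

    def test_temperature_outside_range_rejected(self, wt, capsid):
        with pytest.raises(ValueError, match="outside the defined range"):
            make_saxs_profile(wt, capsid, T=80.0, seed=0)

    def test_narrow_grid_rejected(self, wt, capsid):
        with pytest.raises(ValueError, match="must cover"):
            make_saxs_profile(wt, capsid, T=25.0, seed=0, q_min=0.1)

    def test_seed_determinism(self, wt, capsid):
        a = make_saxs_profile(wt, capsid, T=25.0, n_scans=3, seed=42)
        b = make_saxs_profile(wt, capsid, T=25.0, n_scans=3, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.I, y.I)


class TestTemperatureSeries:
    def test_no_transition_zero_noise_is_one_line(self, l78_noiseless):
        T = np.arange(10.0, 41.0, 5.0)
        s = make_temperature_series(l78_noiseless, "saxs_area", T, 3, seed=0)
        resid = s.A - np.polyval(np.polyfit(s.T, s.A, 1), s.T)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_zero_noise_enthalpy_jump_is_exact(self, wt_noiseless, itc_grid):
        s = make_temperature_series(wt_noiseless, "itc_enthalpy", itc_grid,
                                    3, seed=0)
        i32 = np.flatnonzero(s.T == 32.0)[0]
        i34 = np.flatnonzero(s.T == 34.0)[0]
        # remove the pre/post slopes to isolate the discontinuity
        step = (s.dH[i34] - wt_noiseless.dH_slope_post_J_per_C * 1.0) - (
            s.dH[i32] + wt_noiseless.dH_slope_pre_J_per_C * 1.0
        )
        assert step == pytest.approx(wt_noiseless.dH_jump_J, rel=1e-12)

    def test_detection_rate_for_20mM_area_series(self):
        """WT_Mg20 area series at declared noise: T*=37 C within one grid
        step in >=95% of 200 seeds."""
        from phagetrans import detect_transition

        preset = get_preset("WT_Mg20")
        T = np.arange(18.0, 45.0, 2.0)
        hits = 0
        for seed in range(200):
            cp = detect_transition(
                make_temperature_series(preset, "saxs_area", T, 6, seed=seed)
            )
            if cp.detected and abs(cp.t_star_C - 37.0) <= 2.0:
                hits += 1
        assert hits >= 190

    def test_grid_validation(self, wt):
        with pytest.raises(ValueError, match=">= 6 points"):
            make_temperature_series(wt, "itc_enthalpy", [20, 25, 30], 3, 0)
        with pytest.raises(ValueError, match="each side"):
            make_temperature_series(wt, "itc_enthalpy",
                                    [18, 20, 22, 24, 26, 28, 30, 31], 3, 0)


class TestThermogramGenerator:
    def test_buffer_into_buffer_with_zero_heat_integrates_to_zero(self):
        preset = get_preset("WT_Mg10").noiseless()
        from dataclasses import replace

        zeroed = replace(
            preset,
            itc=replace(
                preset.itc,
                control_heats_ucal={
                    "phage_into_buffer": 0.0,
                    "buffer_into_lamb": 0.0,
                    "buffer_into_buffer": 0.0,
                },
            ),
        )
        trace = make_thermogram(zeroed, T=25.0, n_injections=4,
                                role="buffer_into_buffer", seed=0)
        np.testing.assert_allclose(integrate_injections(trace), 0.0,
                                   atol=1e-9)

    def test_pulses_integrate_to_true_heats(self, wt):
        """At the declared baseline noise the per-injection heat is dominated
        by quiet-window baseline error; the mean over injections recovers the
        true heat."""
        trace = make_thermogram(wt, T=30.0, n_injections=5, role="sample",
                                seed=2)
        got = integrate_injections(trace)
        true = trace.meta["true_heats_ucal"]
        assert np.mean(got) == pytest.approx(np.mean(true), rel=0.2)

    def test_seed_determinism(self, wt):
        a = make_thermogram(wt, T=30.0, n_injections=3, seed=8)
        b = make_thermogram(wt, T=30.0, n_injections=3, seed=8)
        np.testing.assert_array_equal(a.P, b.P)


class TestAveragingPipelineDeterminism:
    def test_scan_averaging_reproducible(self, wt, capsid):
        runs = [
            average_scans(
                make_saxs_profile(wt, capsid, T=25.0, n_scans=10, seed=5)
            ).I
            for _ in range(2)
        ]
        np.testing.assert_array_equal(runs[0], runs[1])
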