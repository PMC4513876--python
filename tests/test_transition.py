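"""Changepoint detection of T*, transition enthalpy, per-bp bound."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phagetrans import (
    EnthalpySeries,
    compare_modalities,
    detect_transition,
    get_preset,
    make_temperature_series,
    per_bp_lower_bound,
    transition_enthalpy,
)
from phagetrans.peaks import AreaSeries


def series(T, y, se=None):
    T = np.asarray(T, float)
    se = np.zeros_like(T) if se is None else np.asarray(se, float)
    return AreaSeries(T, np.asarray(y, float), se)


def two_segment(T, t_star, jump, slope_pre=-0.01, slope_post=-0.001):
    T = np.asarray(T, float)
    pre = 1.0 + slope_pre * (T - T[0])
    pre_at_star = 1.0 + slope_pre * (t_star - T[0])
    post = pre_at_star - jump + slope_post * (T - t_star)
    return np.where(T < t_star, pre, post)


class TestDetectTransition:
    def test_pure_noiseless_line_not_detected(self):
        T = np.arange(18.0, 43.0, 2.0)
        cp = detect_transition(series(T, 2.0 - 0.01 * T))
        assert not cp.detected
        assert cp.t_star_C is None

    def test_noiseless_two_segment_break_and_jump_exact(self):
        T = np.arange(18.0, 43.0, 2.0)
        cp = detect_transition(series(T, two_segment(T, 33.0, jump=0.5)))
        assert cp.detected
        assert cp.t_star_C == pytest.approx(33.0)
        assert cp.jump == pytest.approx(0.5, rel=1e-9)
        assert cp.rss_two <= cp.rss_one

    def test_detection_power_at_preset_noise(self, wt, itc_grid):
        """WT 10 mM ITC series: detected within one grid step in >=95% of
        200 seeded runs."""
        hits = 0
        for seed in range(200):
            s = make_temperature_series(wt, "itc_enthalpy", itc_grid,
                                        n_rep=6, seed=seed)
            cp = detect_transition(s)
            if cp.detected and abs(cp.t_star_C - 33.0) <= 2.0:
                hits += 1
        assert hits >= 190

    def test_false_detection_rate_bounded_by_alpha(self):
        """Pure line plus iid noise: detection rate <= alpha (500 seeds,
        binomial slack)."""
        T = np.arange(18.0, 43.0, 2.0)
        rng = np.random.default_rng(12345)
        alpha = 0.05
        false_hits = sum(
            detect_transition(
                series(T, 2.0 - 0.01 * T + rng.normal(0, 0.05, T.size),
                       se=np.full(T.size, 0.05)),
                alpha=alpha,
            ).detected
            for _ in range(500)
        )
        # alpha + 3 binomial sigmas at p = alpha
        bound = 500 * alpha + 3 * np.sqrt(500 * alpha * (1 - alpha))
        assert false_hits <= bound

    def test_break_estimate_invariant_to_affine_rescaling(self):
        T = np.arange(18.0, 43.0, 2.0)
        rng = np.random.default_rng(3)
        y = two_segment(T, 33.0, 0.4) + rng.normal(0, 0.01, T.size)
        cp1 = detect_transition(series(T, y))
        cp2 = detect_transition(series(T, 7.5 * y - 123.0))
        assert cp1.t_star_C == cp2.t_star_C
        assert cp2.jump == pytest.approx(7.5 * cp1.jump, rel=1e-9)

    def test_jump_sign_matches_generating_law(self, wt, itc_grid):
        """ITC: dH rises at T* (left-minus-right negative); SAXS area drops
        (left-minus-right positive)."""
        enth = make_temperature_series(wt, "itc_enthalpy", itc_grid, 6, seed=0)
        area = make_temperature_series(wt, "saxs_area", itc_grid, 6, seed=0)
        assert detect_transition(enth).jump < 0  # dH jumps toward zero
        assert detect_transition(area).jump > 0  # area drops

    def test_gap_values_are_omitted(self):
        T = np.arange(18.0, 43.0, 2.0)
        y = two_segment(T, 33.0, 0.5)
        y[3] = np.nan
        cp = detect_transition(series(T, y))
        assert cp.detected
        assert cp.n_points == T.size - 1
        assert cp.t_star_C == pytest.approx(33.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            detect_transition(series([1, 2, 3, 4, 5], np.ones(5)))


class TestTransitionEnthalpy:
    def test_unit_conversion_of_jump(self):
        """|jump| 7.61e-17 J at 33 C -> 1.80e4 kT/virion."""
        T = np.arange(18.0, 43.0, 2.0)
        pre = -1e-17 * (T - 18.0)
        pre_at_star = -1e-17 * (33.0 - 18.0)
        post = pre_at_star + 7.61e-17 - 1e-18 * (T - 33.0)
        dH = np.where(T < 33.0, pre, post)
        s = EnthalpySeries(T, dH, np.zeros_like(T), np.ones(T.size, int))
        te = transition_enthalpy(detect_transition(s))
        assert te.kT_per_virion == pytest.approx(1.80e4, rel=2e-3)

    def test_undetected_rejected(self):
        T = np.arange(18.0, 43.0, 2.0)
        cp = detect_transition(series(T, 2.0 - 0.01 * T))
        with pytest.raises(ValueError, match="no transition"):
            transition_enthalpy(cp)

    def test_round_trip_recovers_preset_jump(self, wt, itc_grid):
        """Detected transition enthalpy ~ preset discontinuity within 5%
        at the declared noise (mean over seeds)."""
        vals = [
            transition_enthalpy(
                detect_transition(
                    make_temperature_series(wt, "itc_enthalpy", itc_grid,
                                            6, seed=seed)
                )
            ).J_per_virion
            for seed in range(30)
        ]
        assert np.mean(vals) == pytest.approx(wt.dH_jump_J, rel=0.05)


class TestPerBpLowerBound:
    def test_headline_estimate(self):
        """1.8e4 kT over 6% of 48000 bp -> 6.25 kT/bp (printed as ~6)."""
        assert per_bp_lower_bound(1.8e4) == pytest.approx(6.25)

    def test_full_genome_fraction(self):
        assert per_bp_lower_bound(1.8e4, fraction=1.0) == pytest.approx(0.375)

    @given(st.floats(0.01, 0.5))
    def test_doubling_fraction_halves_the_bound(self, frac):
        one = per_bp_lower_bound(1.8e4, fraction=frac)
        two = per_bp_lower_bound(1.8e4, fraction=2 * frac)
        assert two == pytest.approx(one / 2)


class TestCompareModalities:
    def test_identical_results_differ_by_zero(self, wt, itc_grid):
        s = make_temperature_series(wt, "itc_enthalpy", itc_grid, 6, seed=0)
        cp = detect_transition(s)
        assert compare_modalities(cp, cp) == 0.0

    def test_shared_t_star_agreement_across_modalities(self, wt, itc_grid):
        """ITC and SAXS detections agree within one grid step in >=90% of
        seeded runs."""
        hits, total = 0, 0
        for seed in range(100):
            itc_cp = detect_transition(
                make_temperature_series(wt, "itc_enthalpy", itc_grid, 6,
                                        seed=seed)
            )
            saxs_cp = detect_transition(
                make_temperature_series(wt, "saxs_area", itc_grid, 6,
                                        seed=seed + 10_000)
            )
            if itc_cp.detected and saxs_cp.detected:
                total += 1
                if abs(compare_modalities(itc_cp, saxs_cp)) <= 2.0:
                    hits += 1
        assert total >= 90
        assert hits / total >= 0.9

    def test_undetected_side_rejected(self, wt, itc_grid):
        cp = detect_transition(
            make_temperature_series(wt, "itc_enthalpy", itc_grid, 6, seed=0)
        )
        flat = detect_transition(
            make_temperature_series(
                get_preset("L94_Mg10"), "itc_enthalpy", itc_grid, 6, seed=0
            )
        )
        with pytest.raises(ValueError, match="both modalities"):
            compare_modalities(cp, flat)
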