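import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemaquant import (
    DilutionSeries,
    FitError,
    QuantitationError,
    amount_in_well,
    elisa_conc,
    exposure_dose,
    fit_standard_curve,
    hau_from_well,
    pha_conc_hemagglutination,
    reduction_ratio,
)

STANDARD_AMOUNTS = [0.0, 12.5, 25.0, 50.0, 100.0, 200.0, 300.0]


class TestDilutionBookkeeping:
    def test_purified_control_well_10_holds_203_ng(self):
        series = DilutionSeries(start_conc_ng_per_ul=1040.0)  # 1.04 mg/mL
        assert amount_in_well(series, 10) == pytest.approx(203.125)

    def test_powder_extract_wells_14_and_15(self):
        series = DilutionSeries.from_w_over_v(10.0, n_wells=24)
        assert series.start_conc_ng_per_ul == 100_000.0
        assert amount_in_well(series, 14) == pytest.approx(1220.703125)
        assert amount_in_well(series, 15) == pytest.approx(610.3515625)

    def test_first_well_undiluted(self):
        series = DilutionSeries(500.0, retained_volume_ul=100.0)
        assert amount_in_well(series, 1) == 500.0 * 100.0

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            amount_in_well(DilutionSeries(100.0, n_wells=12), 13)

    @given(
        start=st.floats(min_value=1.0, max_value=1e6),
        f=st.floats(min_value=1.5, max_value=10.0),
        n=st.integers(min_value=1, max_value=23),
    )
    @settings(deadline=None, max_examples=100)
    def test_stepwise_ratio_is_exactly_f(self, start, f, n):
        s = DilutionSeries(start, dilution_factor=f, n_wells=24)
        assert amount_in_well(s, n) / amount_in_well(s, n + 1) == pytest.approx(f)
        assert amount_in_well(s, n) > amount_in_well(s, n + 1)

    @given(n=st.integers(min_value=1, max_value=24))
    @settings(deadline=None, max_examples=50)
    def test_titer_times_amount_conserves_load(self, n):
        """HAU x amount in the last positive well equals the well-1 load."""
        s = DilutionSeries(1040.0, n_wells=24)
        load = s.start_conc_ng_per_ul * s.retained_volume_ul
        assert hau_from_well(n) * amount_in_well(s, n) == pytest.approx(load)


class TestHau:
    @pytest.mark.parametrize("well, hau", [(10, 512), (14, 8192), (1, 1)])
    def test_two_fold_titers(self, well, hau):
        assert hau_from_well(well, 2) == hau


class TestHemagglutinationConc:
    def test_raw_bean_extract_327_mg_per_g(self):
        series = DilutionSeries.from_w_over_v(10.0, n_wells=24)
        q = pha_conc_hemagglutination(series, first_negative=15, theta_ng=200.0)
        assert q.powder_ng_first_negative == pytest.approx(610.3515625)
        assert q.conc_mg_per_g == pytest.approx(200.0 / 610.3515625 * 1000.0)
        assert 327.0 <= q.conc_mg_per_g <= 327.9

    def test_pure_analyte_limit_is_1000_mg_per_g(self):
        series = DilutionSeries(2.0, n_wells=12)  # 200 ng in well 1
        q = pha_conc_hemagglutination(series, first_negative=1, theta_ng=200.0)
        assert q.conc_mg_per_g == pytest.approx(1000.0)

    def test_theta_linearity(self):
        series = DilutionSeries.from_w_over_v(10.0, n_wells=24)
        full = pha_conc_hemagglutination(series, 15, theta_ng=200.0)
        half = pha_conc_hemagglutination(series, 15, theta_ng=100.0)
        assert half.conc_mg_per_g == pytest.approx(full.conc_mg_per_g / 2.0)

    def test_never_negative_series_is_right_censored(self):
        series = DilutionSeries.from_w_over_v(10.0, n_wells=12)
        q = pha_conc_hemagglutination(series, first_negative=None)
        assert q.censored and q.display.startswith(">=")


class TestStandardCurve:
    def test_noise_free_slope_recovered_exactly(self):
        y = [0.0039 * x for x in STANDARD_AMOUNTS]
        curve = fit_standard_curve(STANDARD_AMOUNTS, y)
        assert curve.slope_au_per_ng == pytest.approx(0.0039, abs=1e-12)
        assert curve.intercept_au == pytest.approx(0.0, abs=1e-12)
        assert curve.r2 == pytest.approx(1.0)
        assert curve.slope_ci95[0] <= curve.slope_au_per_ng <= curve.slope_ci95[1]

    def test_replicates_enter_individually(self):
        """Triplicates are not averaged: residual df reflects 21 points."""
        rng = np.random.default_rng(0)
        x = np.repeat(STANDARD_AMOUNTS, 3)
        y = 0.0039 * x + rng.normal(0, 0.01, x.size)
        curve = fit_standard_curve(x, y)
        assert curve.df_resid == x.size - 2

    def test_degenerate_designs_rejected(self):
        with pytest.raises(FitError):
            fit_standard_curve([50.0] * 5, [0.1] * 5)
        with pytest.raises(FitError):
            fit_standard_curve([0.0, 100.0], [0.0, 0.39])

    def test_slope_bias_below_1pct_over_replicates(self):
        """Parameter recovery: OLS slope is unbiased at 0.01 AU noise."""
        rng = np.random.default_rng(11)
        x = np.repeat(STANDARD_AMOUNTS, 3)
        slopes = []
        for _ in range(1000):
            y = 0.0039 * x + rng.normal(0, 0.01, x.size)
            slopes.append(fit_standard_curve(x, y).slope_au_per_ng)
        assert abs(np.mean(slopes) - 0.0039) / 0.0039 < 0.01


class TestElisaConc:
    def _curve(self):
        y = [0.0039 * x for x in STANDARD_AMOUNTS]
        return fit_standard_curve(STANDARD_AMOUNTS, y)

    def test_hand_arithmetic_chain(self):
        """0.78 AU at slope 0.0039 is 200 ng in the well; at 10% w/v powder
        load and no dilution that is 0.02 mg active lectin per g powder."""
        res = elisa_conc(0.78, self._curve(), dilution_factor=1.0)
        assert res.ng_in_well == pytest.approx(200.0)
        assert res.conc_mg_per_g == pytest.approx(0.02)
        assert res.flags == ()

    def test_blank_absorbance_censored_below_lloq(self):
        res = elisa_conc(0.0, self._curve(), dilution_factor=1.0)
        assert res.censored_below_lloq
        # censored value is the LLOQ-equivalent bound, not zero
        assert res.conc_mg_per_g == pytest.approx(15.0 / 100.0 / 0.1 / 1000.0)

    def test_dilution_factor_linearity(self):
        r1 = elisa_conc(0.78, self._curve(), dilution_factor=1.0)
        r2 = elisa_conc(0.78, self._curve(), dilution_factor=2.0)
        assert r2.conc_mg_per_g == pytest.approx(2.0 * r1.conc_mg_per_g)

    def test_above_top_standard_flagged(self):
        res = elisa_conc(0.0039 * 400.0, self._curve(), dilution_factor=1.0)
        assert "above_max_standard" in res.flags

    def test_zero_slope_curve_refuses_quantitation(self):
        flat = fit_standard_curve(STANDARD_AMOUNTS, [0.0] * len(STANDARD_AMOUNTS))
        assert flat.slope_au_per_ng == pytest.approx(0.0, abs=1e-15)
        with pytest.raises(QuantitationError):
            elisa_conc(0.5, flat, dilution_factor=1.0)


class TestDoseArithmetic:
    def test_four_seed_dose(self):
        d = exposure_dose(223.06, 2.44)
        assert d.dose_mg == pytest.approx(544.27, abs=0.05)

    def test_canned_bean_dose(self):
        d = exposure_dose(0.0049, 94.0)
        assert d.dose_mg == pytest.approx(0.4606)

    def test_zero_mass_zero_dose(self):
        assert exposure_dose(223.06, 0.0).dose_mg == 0.0

    def test_reduction_ratio_canned_vs_raw(self):
        assert reduction_ratio(0.0049, 223.06) == pytest.approx(0.0022, abs=0.0002)
        assert reduction_ratio(0.0049, 223.06) < 1.0
        assert reduction_ratio(5.0, 5.0) == 100.0
        assert reduction_ratio(0.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            reduction_ratio(1.0, 0.0)
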